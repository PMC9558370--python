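"""Readers and writers for the package's file formats.

Ligand libraries come in as SMILES files (one molecule per line, optional
tab-separated id) or SDF (3-D coordinates preserved); affinity tables and
feature blocks travel as comma-separated CSV with a header row, ligand ids
in the first column, and free energies always in kcal/mol.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import FeatureBlock, Ligand, SelectionBatch

__all__ = [
    "read_smiles_file",
    "write_smiles_file",
    "read_sdf",
    "read_affinity_table",
    "write_feature_block",
    "read_feature_block",
    "write_batches",
]


def read_smiles_file(path: str | Path) -> list[Ligand]:
    """One SMILES per line; an optional second tab-separated field is the
    ligand id (default ``mol_<line>``). Blank lines and ``#`` comments are
    skipped."""
    ligands = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            lig_id = parts[1].strip() if len(parts) > 1 else f"mol_{lineno}"
            ligands.append(Ligand(ligand_id=lig_id, smiles=smiles))
    return ligands


def write_smiles_file(ligands: Sequence[Ligand], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lig in ligands:
            fh.write(f"{lig.smiles}\t{lig.ligand_id}\n")


def read_sdf(path: str | Path) -> list[Ligand]:
    """Read an SDF; heavy-atom coordinates are kept for voxel encodings."""
    from rdkit import Chem

    ligands = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unparseable molecule at index {i}")
        lig_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        coords = None
        if mol.GetNumConformers():
            coords = np.asarray(mol.GetConformer().GetPositions())
        ligands.append(Ligand(
            ligand_id=lig_id or f"mol_{i}",
            smiles=Chem.MolToSmiles(mol),
            coords=coords,
        ))
    return ligands


def read_affinity_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """CSV with columns ligand_id, dg[, uncertainty] → lookup-oracle table."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    dg_col = "dg" if "dg" in cols else "dg_true" if "dg_true" in cols else None
    if "ligand_id" not in cols or dg_col is None:
        raise ValueError(f"{path}: needs ligand_id and dg (or dg_true) columns")
    unc = df["uncertainty"] if "uncertainty" in cols else 0.0 * df[dg_col]
    return {
        str(lid): (float(dg), float(u))
        for lid, dg, u in zip(df["ligand_id"], df[dg_col], unc)
    }


def write_feature_block(block: FeatureBlock, path: str | Path) -> None:
    df = pd.DataFrame(block.matrix, columns=block.feature_names)
    df.insert(0, "ligand_id", block.ligand_ids)
    df.to_csv(path, index=False)


def read_feature_block(path: str | Path, name: str) -> FeatureBlock:
    df = pd.read_csv(path)
    if "ligand_id" not in df.columns:
        raise ValueError(f"{path}: no ligand_id column")
    ids = [str(x) for x in df["ligand_id"]]
    data = df.drop(columns="ligand_id")
    return FeatureBlock(
        name=name,
        matrix=data.to_numpy(float),
        feature_names=[str(c) for c in data.columns],
        ligand_ids=ids,
    )


def write_batches(batches: Sequence[SelectionBatch], path: str | Path) -> None:
    """Per-iteration selections as CSV (iteration, strategy, ligand, rank)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "strategy", "ligand_id", "rank",
                         "rationale"])
        for batch in batches:
            rationale = batch.rationale or [""] * len(batch.ligand_ids)
            for rank, (lid, why) in enumerate(
                zip(batch.ligand_ids, rationale), start=1
            ):
                writer.writerow([batch.iteration, batch.strategy, lid, rank,
                                 why])
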