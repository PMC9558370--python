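"""Fixed-size numeric representations of ligands.

Two representations are computed here: the ``2D_3D`` descriptor block
(constitutional, topological, electrotopological and surface-area
descriptors plus folded fingerprints, with optional shape descriptors when
3-D coordinates are available) and the ``atom_hot`` voxel encoding
(per-element atom counts over a cubic grid, flattened to a vector).
Protein–ligand interaction blocks (PLEC fingerprints, force-field
interaction energies) require a protein structure and an MD stack, so they
are ingested as precomputed matrices via :func:`attach_external_block`.

Featurization is pure: the output depends only on the ligands and the
catalogue version.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdMolDescriptors
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

from .catalogue import DEFAULT_CATALOGUE
from .containers import FeatureBlock, Ligand, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "compute_2d3d",
    "compute_atom_hot",
    "attach_external_block",
    "standardize",
    "destandardize",
    "rgroup_block",
]


def _mol_from_smiles(smiles: str, ligand_id: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"ligand {ligand_id!r}: unparseable SMILES {smiles!r}")
    return mol


def _mol_with_conformer(mol: Chem.Mol, coords: np.ndarray,
                        ligand_id: str) -> Chem.Mol:
    if coords.shape[0] != mol.GetNumAtoms():
        raise ValueError(
            f"ligand {ligand_id!r}: {coords.shape[0]} coordinates for "
            f"{mol.GetNumAtoms()} atoms"
        )
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    mol = Chem.Mol(mol)
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)
    return mol


def _descriptor_row(mol, names: Sequence[str]) -> list[float]:
    row = []
    for name in names:
        try:
            row.append(float(getattr(Descriptors, name)(mol)))
        except Exception:
            row.append(float("nan"))
    return row


def _fingerprint_row(mol, fingerprints: dict) -> tuple[list[float], list[str]]:
    values: list[float] = []
    names: list[str] = []
    for fp_name, params in fingerprints.items():
        if fp_name == "maccs":
            bits = MACCSkeys.GenMACCSKeys(mol)
            values.extend(float(b) for b in bits)
            names.extend(f"maccs_{i}" for i in range(bits.GetNumBits()))
        elif fp_name == "morgan":
            gen = GetMorganGenerator(radius=params.get("radius", 2),
                                     fpSize=params.get("n_bits", 1024))
            bits = gen.GetFingerprint(mol)
            values.extend(float(b) for b in bits)
            names.extend(f"morgan_{i}" for i in range(bits.GetNumBits()))
        elif fp_name == "bcut2d":
            try:
                vals = rdMolDescriptors.BCUT2D(mol)
            except Exception:
                vals = [float("nan")] * 8
            values.extend(float(v) for v in vals)
            names.extend(f"bcut2d_{i}" for i in range(len(vals)))
        else:
            raise ValueError(f"unknown fingerprint {fp_name!r} in catalogue")
    return values, names


def _drop_nonfinite_columns(matrix: np.ndarray,
                            names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Columns uncomputable for any ligand are dropped, not imputed."""
    finite = np.isfinite(matrix).all(axis=0)
    if not finite.all():
        dropped = [n for n, ok in zip(names, finite) if not ok]
        logger.info("dropping %d non-finite feature columns: %s%s",
                    len(dropped), ", ".join(dropped[:8]),
                    "..." if len(dropped) > 8 else "")
    return matrix[:, finite], [n for n, ok in zip(names, finite) if ok]


def compute_2d3d(
    ligands: Sequence[Ligand],
    catalogue: Optional[dict] = None,
    block_name: str = "2D_3D",
) -> FeatureBlock:
    """Compute the concatenated descriptor + fingerprint block.

    Shape descriptors from the catalogue's 3-D list are included only when
    every ligand carries coordinates. Columns that come out non-finite for
    any ligand are dropped and logged.
    """
    if catalogue is None:
        catalogue = DEFAULT_CATALOGUE
    if not ligands:
        raise ValueError("no ligands to featurize")
    names_2d = list(catalogue.get("descriptors_2d", []))
    names_3d = list(catalogue.get("descriptors_3d", []))
    fingerprints = dict(catalogue.get("fingerprints", {}))
    use_3d = bool(names_3d) and all(l.coords is not None for l in ligands)
    if names_3d and not use_3d:
        logger.info("3-D descriptors skipped: not all ligands carry coordinates")

    rows: list[list[float]] = []
    fp_names: list[str] = []
    for lig in ligands:
        mol = _mol_from_smiles(lig.smiles, lig.ligand_id)
        row = _descriptor_row(mol, names_2d)
        if use_3d:
            mol3d = _mol_with_conformer(mol, lig.coords, lig.ligand_id)
            for name in names_3d:
                try:
                    row.append(float(getattr(rdMolDescriptors, name)(mol3d)))
                except Exception:
                    row.append(float("nan"))
        fp_values, fp_names = _fingerprint_row(mol, fingerprints)
        row.extend(fp_values)
        rows.append(row)

    names = names_2d + (names_3d if use_3d else []) + fp_names
    matrix, names = _drop_nonfinite_columns(
        np.asarray(rows, dtype=float), names
    )
    return FeatureBlock(
        name=block_name,
        matrix=matrix,
        feature_names=names,
        ligand_ids=[l.ligand_id for l in ligands],
    )


def compute_atom_hot(
    ligands: Sequence[Ligand],
    grid: VoxelGrid,
    surface_mask: Optional[np.ndarray] = None,
    block_name: str = "atom_hot",
) -> FeatureBlock:
    """Count ligand atoms of each element per voxel, flattened to a vector.

    Elements outside ``grid.elements`` are pooled into an ``other`` channel;
    atoms outside the grid are tallied in a per-element overflow bin rather
    than silently dropped, so per-element counts are conserved. With
    ``surface_mask`` (one boolean per voxel, C-order over the grid dims),
    voxel columns are restricted to the masked voxels; overflow bins are
    always kept.
    """
    channels = list(grid.elements) + ["other"]
    chan_index = {e: i for i, e in enumerate(grid.elements)}
    n_vox = grid.n_voxels
    if surface_mask is not None:
        surface_mask = np.asarray(surface_mask, dtype=bool).ravel()
        if surface_mask.size != n_vox:
            raise ValueError(
                f"surface mask has {surface_mask.size} entries for "
                f"{n_vox} voxels"
            )

    dims = np.asarray(grid.dims)
    rows = np.zeros((len(ligands), len(channels) * (n_vox + 1)))
    unknown_elements: set[str] = set()
    for r, lig in enumerate(ligands):
        if lig.coords is None:
            raise ValueError(
                f"ligand {lig.ligand_id!r}: atom-hot encoding needs coordinates"
            )
        mol = _mol_from_smiles(lig.smiles, lig.ligand_id)
        if lig.coords.shape[0] != mol.GetNumAtoms():
            raise ValueError(
                f"ligand {lig.ligand_id!r}: coordinate/atom count mismatch"
            )
        idx = grid.voxel_index(lig.coords)
        for atom, (i, j, k) in zip(mol.GetAtoms(), idx):
            sym = atom.GetSymbol()
            c = chan_index.get(sym, len(grid.elements))
            if c == len(grid.elements):
                unknown_elements.add(sym)
            if i < 0:  # out of grid bounds
                flat = n_vox
            else:
                flat = int(i * dims[1] * dims[2] + j * dims[2] + k)
            rows[r, c * (n_vox + 1) + flat] += 1
    if unknown_elements:
        logger.info("elements pooled into 'other' channel: %s",
                    ", ".join(sorted(unknown_elements)))

    names = []
    for e in channels:
        for i in range(grid.dims[0]):
            for j in range(grid.dims[1]):
                for k in range(grid.dims[2]):
                    names.append(f"{e}@{i},{j},{k}")
        names.append(f"{e}@overflow")

    if surface_mask is not None:
        keep = np.concatenate(
            [np.append(surface_mask, True) for _ in channels]
        )
        rows = rows[:, keep]
        names = [n for n, k in zip(names, keep) if k]

    return FeatureBlock(
        name=block_name,
        matrix=rows,
        feature_names=names,
        ligand_ids=[l.ligand_id for l in ligands],
    )


def attach_external_block(
    path,
    name: str,
    library: Sequence[Ligand],
) -> FeatureBlock:
    """Ingest a precomputed per-ligand feature matrix from CSV.

    The CSV must carry a ``ligand_id`` column covering the whole library;
    rows are reordered to library order. Extra ligands in the file are
    ignored with a warning, missing ligands are a hard error.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if "ligand_id" not in df.columns:
        raise ValueError(f"{path}: no ligand_id column")
    df = df.set_index("ligand_id")
    lib_ids = [l.ligand_id for l in library]
    missing = [lid for lid in lib_ids if lid not in df.index]
    if missing:
        raise ValueError(
            f"{path}: missing features for ligands: {', '.join(missing[:10])}"
        )
    extra = df.index.difference(lib_ids)
    if len(extra):
        logger.warning("%s: ignoring %d ligands not in the library",
                       path, len(extra))
    df = df.loc[lib_ids]
    matrix = df.to_numpy(dtype=float)
    if not np.isfinite(matrix).all():
        raise ValueError(f"{path}: non-finite feature values")
    return FeatureBlock(
        name=name,
        matrix=matrix,
        feature_names=[str(c) for c in df.columns],
        ligand_ids=lib_ids,
    )


def standardize(block: FeatureBlock, fit_ids: Sequence[str]) -> FeatureBlock:
    """Zero-mean/unit-variance transform fitted on ``fit_ids`` rows only.

    The affine transform is fitted on the given subset (the training ligands,
    to avoid leakage) and applied to all rows. Constant columns on the
    fitting set are centered but left unscaled.
    """
    if len(fit_ids) == 0:
        raise ValueError("standardize needs a non-empty fitting set")
    fit_rows = block.rows(fit_ids)
    means = fit_rows.mean(axis=0)
    stds = fit_rows.std(axis=0)
    constant = stds <= 1e-12 * np.maximum(1.0, np.abs(means))
    if constant.any():
        logger.info("block %r: %d constant columns centered but not scaled",
                    block.name, int(constant.sum()))
    scale = np.where(constant, 1.0, stds)
    return dataclasses.replace(
        block,
        matrix=(block.matrix - means) / scale,
        standardized=True,
        column_means=means,
        column_stds=scale,
    )


def destandardize(block: FeatureBlock) -> FeatureBlock:
    """Invert :func:`standardize` using the stored column statistics."""
    if not block.standardized:
        raise ValueError("block is not standardized")
    return dataclasses.replace(
        block,
        matrix=block.matrix * block.column_stds + block.column_means,
        standardized=False,
        column_means=None,
        column_stds=None,
    )


def rgroup_block(
    ligands: Sequence[Ligand],
    catalogue: Optional[dict] = None,
    block_name: str = "2D_3D_rgroup",
) -> FeatureBlock:
    """The descriptor pipeline applied to R-group substructures only.

    Useful for scaffold-sharing libraries where whole-ligand descriptors are
    dominated by the common core. Descriptors that cannot be computed for
    the much smaller substructures are dropped by the shared pipeline.
    """
    missing = [l.ligand_id for l in ligands if not l.rgroup_smiles]
    if missing:
        raise ValueError(
            f"ligands lack rgroup_smiles: {', '.join(missing[:10])}"
        )
    proxies = [
        Ligand(ligand_id=l.ligand_id, smiles=l.rgroup_smiles,
               provenance=l.provenance)
        for l in ligands
    ]
    return compute_2d3d(proxies, catalogue=catalogue, block_name=block_name)
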