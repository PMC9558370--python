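"""Synthetic libraries and affinity landscapes for testing the pipeline.

Real lead-optimization series have a characteristic statistical shape: a
handful of clusters of chemically similar ligands, a small minority of
strong binders concentrated in a few of those clusters, and an oracle whose
answers carry roughly 1 kcal/mol of noise. :func:`generate_landscape`
builds that shape directly in a latent feature space, so the active
learning machinery — models, selection, metrics — can be exercised without
external data and without the chemistry toolkit. The latent features stand
in for a ligand representation and are consumed as an ordinary
:class:`~alchemspace.containers.FeatureBlock`.

A small set of real molecules sharing a pyridine core
(:func:`fixture_molecules`) covers the chemistry-dependent code paths
(decomposition, enumeration, descriptor and voxel featurization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureBlock, Ligand

__all__ = [
    "SyntheticLandscape",
    "generate_landscape",
    "landscape_views",
    "export_landscape",
    "load_landscape",
    "fixture_molecules",
    "FIXTURE_CORE",
]


@dataclass
class SyntheticLandscape:
    """A latent-space ligand library with a known affinity landscape."""

    n_ligands: int
    features: FeatureBlock
    cluster_assignments: np.ndarray
    dg_true: np.ndarray  # kcal/mol, aligned with features.ligand_ids
    strong_threshold: float
    strong_fraction: float
    strong_clusters: tuple[int, ...]
    seed: int

    @property
    def ligand_ids(self) -> list[str]:
        return self.features.ligand_ids

    def truth(self) -> dict[str, float]:
        return {lid: float(dg)
                for lid, dg in zip(self.ligand_ids, self.dg_true)}

    def strong_ids(self) -> list[str]:
        return [lid for lid, dg in zip(self.ligand_ids, self.dg_true)
                if dg < self.strong_threshold]


def generate_landscape(
    n_ligands: int = 2000,
    n_clusters: int = 8,
    n_strong_clusters: int = 3,
    strong_fraction: float = 0.025,
    dg_range: tuple[float, float] = (-17.0, -6.0),
    noise_free: bool = False,
    n_features: int = 12,
    seed: int = 0,
) -> SyntheticLandscape:
    """Gaussian clusters in latent space with a cluster-dependent ΔG map.

    Ligands form ``n_clusters`` isotropic Gaussian clusters; ΔG is a smooth
    function of latent position — a per-cluster base level plus a linear
    term in the offset from the cluster center — with mild sinusoidal
    ruggedness unless ``noise_free``. The first ``n_strong_clusters``
    clusters get low base levels, the rest high ones, so strong binders are
    confined to a few clusters. Free energies are affinely rescaled to span
    ``dg_range`` and the strong threshold is placed so that exactly
    ⌈strong_fraction · n⌉ ligands fall below it, all inside strong
    clusters. Bit-reproducible under ``seed``.
    """
    if not 0 < strong_fraction < 0.5:
        raise ValueError("strong_fraction must be in (0, 0.5)")
    if n_strong_clusters > n_clusters or n_strong_clusters < 1:
        raise ValueError("need 1 <= n_strong_clusters <= n_clusters")
    if dg_range[0] >= dg_range[1]:
        raise ValueError("dg_range must be (low, high) with low < high")
    n_strong = math.ceil(strong_fraction * n_ligands)
    if n_strong >= n_ligands * n_strong_clusters / n_clusters / 2:
        raise ValueError(
            "strong_fraction too large for the strong clusters to absorb"
        )

    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_clusters, n_features)) * 6.0
    assignments = rng.integers(0, n_clusters, size=n_ligands)
    offsets = rng.standard_normal((n_ligands, n_features))
    X = centers[assignments] + offsets

    strong_clusters = tuple(range(n_strong_clusters))
    base = np.where(
        np.arange(n_clusters) < n_strong_clusters,
        rng.uniform(-15.0, -13.5, size=n_clusters),
        rng.uniform(-10.5, -8.5, size=n_clusters),
    )
    slopes = rng.standard_normal((n_clusters, n_features))
    slopes *= 0.8 / np.linalg.norm(slopes, axis=1, keepdims=True)
    dg = base[assignments] + np.einsum(
        "ij,ij->i", slopes[assignments], offsets
    )
    if not noise_free:
        rugged_dirs = rng.standard_normal((n_clusters, n_features))
        rugged_dirs /= np.linalg.norm(rugged_dirs, axis=1, keepdims=True)
        phase = np.einsum("ij,ij->i", rugged_dirs[assignments], offsets)
        dg = dg + 0.25 * np.sin(2.0 * np.pi * phase / 2.0)

    # rescale to span the configured free-energy range exactly
    lo, hi = dg_range
    dg = lo + (dg - dg.min()) * (hi - lo) / (dg.max() - dg.min())

    order = np.sort(dg)
    if order[n_strong - 1] == order[n_strong]:
        raise ValueError("degenerate landscape: tied ΔG at the strong cut")
    threshold = 0.5 * (order[n_strong - 1] + order[n_strong])
    strong_mask = dg < threshold
    if not np.isin(assignments[strong_mask], strong_clusters).all():
        raise ValueError(
            "infeasible parameters: strong binders leak outside the "
            "designated strong clusters; widen dg_range or lower "
            "strong_fraction"
        )

    ids = [f"syn_{i:06d}" for i in range(n_ligands)]
    block = FeatureBlock(
        name="latent",
        matrix=X,
        feature_names=[f"z{j}" for j in range(n_features)],
        ligand_ids=ids,
    )
    return SyntheticLandscape(
        n_ligands=n_ligands,
        features=block,
        cluster_assignments=assignments,
        dg_true=dg,
        strong_threshold=float(threshold),
        strong_fraction=strong_fraction,
        strong_clusters=strong_clusters,
        seed=seed,
    )


def landscape_views(
    landscape: SyntheticLandscape,
    n_views: int = 5,
    seed: int = 0,
    noise_scales: Optional[list[float]] = None,
) -> list[FeatureBlock]:
    """Derived feature blocks acting as alternative ligand representations.

    Each view is a random orthogonal rotation of the latent features plus
    Gaussian feature noise of a view-specific scale, so the views differ in
    informativeness the way real representations do — which gives the
    narrowing strategy a meaningful cross-validation ranking to work with.
    """
    rng = np.random.default_rng(seed)
    if noise_scales is None:
        noise_scales = [0.1 + 0.4 * i / max(1, n_views - 1)
                        for i in range(n_views)]
    if len(noise_scales) != n_views:
        raise ValueError("noise_scales must have one entry per view")
    X = landscape.features.matrix
    d = X.shape[1]
    views = []
    for v in range(n_views):
        q, _ = np.linalg.qr(rng.standard_normal((d, d)))
        noisy = X @ q + noise_scales[v] * rng.standard_normal(X.shape)
        views.append(FeatureBlock(
            name=f"latent_view{v}",
            matrix=noisy,
            feature_names=[f"v{v}_{j}" for j in range(d)],
            ligand_ids=list(landscape.features.ligand_ids),
        ))
    return views


def export_landscape(landscape: SyntheticLandscape, out_dir: str | Path,
                     oracle_kind: str = "synthetic",
                     sigma: float = 1.1, n_replicates: int = 5) -> dict:
    """Write the feature CSV, truth CSV and a ready-to-run config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    feats = pd.DataFrame(landscape.features.matrix,
                         columns=landscape.features.feature_names)
    feats.insert(0, "ligand_id", landscape.ligand_ids)
    feats.to_csv(out_dir / "features.csv", index=False)
    truth = pd.DataFrame({
        "ligand_id": landscape.ligand_ids,
        "dg_true": landscape.dg_true,
        "cluster": landscape.cluster_assignments,
    })
    truth.to_csv(out_dir / "truth.csv", index=False)
    config = {
        "library": {"features": "features.csv", "truth": "truth.csv"},
        "landscape": {
            "n_ligands": landscape.n_ligands,
            "seed": landscape.seed,
            "strong_threshold": landscape.strong_threshold,
            "strong_fraction": landscape.strong_fraction,
            "strong_clusters": list(landscape.strong_clusters),
        },
        "oracle": {
            "kind": oracle_kind,
            "sigma": sigma,
            "n_replicates": n_replicates,
        },
        "policy": "greedy",
        "batch_size": 100,
        "max_iterations": 6,
        "seed": landscape.seed,
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config


def load_landscape(out_dir: str | Path) -> SyntheticLandscape:
    """Rebuild a landscape from :func:`export_landscape` output."""
    out_dir = Path(out_dir)
    with open(out_dir / "config.yaml") as fh:
        config = yaml.safe_load(fh)
    feats = pd.read_csv(out_dir / "features.csv")
    truth = pd.read_csv(out_dir / "truth.csv")
    ids = feats["ligand_id"].tolist()
    meta = config["landscape"]
    block = FeatureBlock(
        name="latent",
        matrix=feats.drop(columns="ligand_id").to_numpy(float),
        feature_names=[c for c in feats.columns if c != "ligand_id"],
        ligand_ids=ids,
    )
    return SyntheticLandscape(
        n_ligands=meta["n_ligands"],
        features=block,
        cluster_assignments=truth["cluster"].to_numpy(int),
        dg_true=truth["dg_true"].to_numpy(float),
        strong_threshold=float(meta["strong_threshold"]),
        strong_fraction=float(meta["strong_fraction"]),
        strong_clusters=tuple(meta["strong_clusters"]),
        seed=int(meta["seed"]),
    )


# ---------------------------------------------------------------------------
# chemistry fixtures

FIXTURE_CORE = "c1ccncc1"  # pyridine scaffold shared by all fixture ligands

# (ligand_id, full SMILES, R-group SMILES) — a congeneric series of
# 4-substituted pyridines whose substituents range from single groups to
# linker + terminus architectures that BRICS can cut.
_FIXTURE_TABLE: tuple[tuple[str, str, str], ...] = (
    ("fix_00", "Cc1ccncc1", "C"),
    ("fix_01", "CCc1ccncc1", "CC"),
    ("fix_02", "CCCc1ccncc1", "CCC"),
    ("fix_03", "OCc1ccncc1", "CO"),
    ("fix_04", "NCc1ccncc1", "CN"),
    ("fix_05", "FC(F)c1ccncc1", "C(F)F"),
    ("fix_06", "ClCc1ccncc1", "CCl"),
    ("fix_07", "COc1ccncc1", "OC"),
    ("fix_08", "CC(C)c1ccncc1", "C(C)C"),
    ("fix_09", "C1CC1c1ccncc1", "C1CC1"),
    ("fix_10", "O=C(O)Cc1ccncc1", "CC(=O)O"),
    ("fix_11", "N#Cc1ccncc1", "C#N"),
    ("fix_12", "OCCc1ccncc1", "CCO"),
    ("fix_13", "CN(C)Cc1ccncc1", "CN(C)C"),
    ("fix_14", "O=C(NC1CC1)c1ccncc1", "C(=O)NC1CC1"),
    ("fix_15", "O=C(Nc1ccccc1)c1ccncc1", "C(=O)Nc1ccccc1"),
    ("fix_16", "CC(=O)Nc1ccncc1", "NC(C)=O"),
    ("fix_17", "O=S(=O)(C)c1ccncc1", "S(C)(=O)=O"),
    ("fix_18", "c1ccc(Cc2ccncc2)cc1", "Cc1ccccc1"),
    ("fix_19", "OC(=O)c1ccncc1", "C(=O)O"),
)


def fixture_molecules(with_coords: bool = True,
                      seed: int = 2024) -> list[Ligand]:
    """The packaged congeneric pyridine series, optionally with embedded
    3-D coordinates (deterministic distance-geometry embedding)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    ligands = []
    for lig_id, smiles, rgroup in _FIXTURE_TABLE:
        coords = None
        if with_coords:
            mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
            if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
                raise RuntimeError(f"embedding failed for {lig_id}")
            mol = Chem.RemoveHs(mol)
            coords = mol.GetConformer().GetPositions()
        ligands.append(Ligand(
            ligand_id=lig_id, smiles=smiles, coords=coords,
            rgroup_smiles=rgroup, provenance="input",
        ))
    return ligands
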