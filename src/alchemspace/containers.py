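"""Core data containers shared across the package.

All free energies are absolute binding free energies in kcal/mol, with more
negative values meaning stronger binding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class Ligand:
    """A library member: identity plus chemistry.

    ``coords`` (Å, one row per atom) are required only for voxel encodings;
    ``rgroup_smiles`` tags the variable substructure for R-group-only
    featurization of scaffold-sharing libraries.
    """

    ligand_id: str
    smiles: str
    coords: Optional[np.ndarray] = None
    rgroup_smiles: Optional[str] = None
    provenance: str = "input"  # input | enumerated | synthetic

    def __post_init__(self) -> None:
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.ndim != 2 or self.coords.shape[1] != 3:
                raise ValueError(
                    f"ligand {self.ligand_id}: coords must be (n_atoms, 3)"
                )


@dataclass
class Fragment:
    """A piece of a decomposed ligand series.

    ``kind`` is "linker" (bonds directly to the core in its source ligand) or
    "terminus" (bonds to a linker). ``smiles_with_attachment`` carries dummy
    atoms marking open valences; ``attachment_sites`` maps each dummy's atom
    index to a site label ("core" for the core-facing site of a linker,
    "branch" for termini-facing sites).
    """

    smiles_with_attachment: str
    kind: str
    origin_ligand_id: str
    attachment_sites: list[tuple[int, str]] = field(default_factory=list)
    core_anchor: Optional[int] = None  # core-atom index this linker bonds to

    def __post_init__(self) -> None:
        if self.kind not in ("linker", "terminus"):
            raise ValueError(f"unknown fragment kind {self.kind!r}")
        if not self.attachment_sites:
            raise ValueError("fragment must carry at least one attachment site")


@dataclass
class AffinityRecord:
    """An oracle answer: ΔG with its standard error and provenance."""

    ligand_id: str
    dg: float
    uncertainty: float = 0.0
    source: str = "experiment"  # experiment | computed | synthetic
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.dg):
            raise ValueError(f"ligand {self.ligand_id}: non-finite dg")
        if self.uncertainty < 0:
            raise ValueError(f"ligand {self.ligand_id}: negative uncertainty")


@dataclass
class FeatureBlock:
    """A named (n_ligands × n_features) matrix aligned to ligand ids.

    Standardization state travels with the block so a transform fitted on the
    training ligands can be applied, and inverted, anywhere downstream.
    """

    name: str
    matrix: np.ndarray
    feature_names: list[str]
    ligand_ids: list[str]
    standardized: bool = False
    column_means: Optional[np.ndarray] = None
    column_stds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape != (len(self.ligand_ids), len(self.feature_names)):
            raise ValueError(
                f"block {self.name!r}: matrix shape {self.matrix.shape} does not "
                f"match {len(self.ligand_ids)} ligands × "
                f"{len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError(f"block {self.name!r}: duplicate feature names")
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise ValueError(f"block {self.name!r}: duplicate ligand ids")

    @property
    def n_ligands(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def row_index(self, ligand_ids: Sequence[str]) -> np.ndarray:
        """Row positions of ``ligand_ids``; raises on unknown ids."""
        lookup = {lid: i for i, lid in enumerate(self.ligand_ids)}
        missing = [lid for lid in ligand_ids if lid not in lookup]
        if missing:
            raise KeyError(
                f"block {self.name!r} lacks features for: {', '.join(missing[:10])}"
            )
        return np.array([lookup[lid] for lid in ligand_ids], dtype=int)

    def rows(self, ligand_ids: Sequence[str]) -> np.ndarray:
        return self.matrix[self.row_index(ligand_ids)]

    def subset_features(self, names: Sequence[str]) -> "FeatureBlock":
        pos = {n: j for j, n in enumerate(self.feature_names)}
        cols = [pos[n] for n in names]
        return dataclasses.replace(
            self,
            matrix=self.matrix[:, cols].copy(),
            feature_names=list(names),
            column_means=None if self.column_means is None else self.column_means[cols],
            column_stds=None if self.column_stds is None else self.column_stds[cols],
        )


@dataclass
class VoxelGrid:
    """A cubic-voxel grid over the binding-site region.

    Atoms are binned with half-open intervals [origin + i·edge,
    origin + (i+1)·edge) along each axis (floor indexing), so an atom sitting
    exactly on a voxel face belongs to the higher-index cell.
    """

    origin: tuple[float, float, float]
    edge: float
    dims: tuple[int, int, int]
    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "H")

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("voxel edge must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must all be >= 1")

    @property
    def n_voxels(self) -> int:
        dx, dy, dz = self.dims
        return dx * dy * dz

    def voxel_index(self, xyz: np.ndarray) -> np.ndarray:
        """Integer (i, j, k) per atom; out-of-bounds atoms get index -1."""
        rel = (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / self.edge
        idx = np.floor(rel).astype(int)
        in_bounds = np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)
        idx[~in_bounds] = -1
        return idx


@dataclass
class SelectionBatch:
    """The outcome of one selection round."""

    iteration: int
    strategy: str
    ligand_ids: list[str]
    rationale: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise ValueError("selection batch contains duplicate ligand ids")
        if self.rationale and len(self.rationale) != len(self.ligand_ids):
            raise ValueError("rationale must align with ligand_ids")
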