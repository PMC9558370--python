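"""Sources of binding free energies for selected batches.

Three oracles are provided:

* :func:`lookup_oracle` — retrospective mode, where measured affinities are
  simply looked up in a table;
* :func:`synthetic_oracle` — an emulator of an alchemical free-energy engine:
  each ligand is "evaluated" by several noisy replicates whose mean and
  standard error become the reported ΔG and uncertainty;
* :class:`ManifestAdapter` — a file-based bridge to an external engine that
  computes relative free energies (ΔΔG) against a reference ligand.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .containers import AffinityRecord, Ligand

__all__ = [
    "lookup_oracle",
    "synthetic_oracle",
    "rel_to_abs",
    "ManifestAdapter",
]


def lookup_oracle(
    batch: Sequence[str],
    table: Mapping[str, tuple[float, float]],
) -> list[AffinityRecord]:
    """Return measured affinities for ``batch``, in batch order.

    ``table`` maps ligand_id → (ΔG, uncertainty), both kcal/mol. A ligand
    missing from the table is a hard error: in retrospective mode every
    library member must have a measured value.
    """
    missing = [lid for lid in batch if lid not in table]
    if missing:
        raise KeyError(
            f"lookup oracle has no affinity for: {', '.join(missing[:10])}"
        )
    return [
        AffinityRecord(
            ligand_id=lid,
            dg=float(table[lid][0]),
            uncertainty=float(table[lid][1]),
            source="experiment",
        )
        for lid in batch
    ]


def synthetic_oracle(
    batch: Sequence[str],
    truth: Mapping[str, float],
    sigma: float = 1.1,
    n_replicates: int = 5,
    seed: int = 0,
    cluster_bias: Optional[Mapping[str, float]] = None,
) -> list[AffinityRecord]:
    """Emulate a replicated free-energy calculation.

    For each ligand, ``n_replicates`` independent Gaussian perturbations of
    the true ΔG with standard deviation ``sigma`` are drawn; the replicate
    mean is reported as ΔG and the replicate standard error as the
    uncertainty. The default ``sigma`` of 1.1 kcal/mol matches the typical
    discrepancy between nonequilibrium alchemical calculations and
    experiment; 5 replicates mirror the usual repeat protocol.

    ``cluster_bias`` optionally adds a fixed per-ligand systematic offset
    (kcal/mol) on top of the random noise, for robustness probes.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    missing = [lid for lid in batch if lid not in truth]
    if missing:
        raise KeyError(
            f"synthetic oracle has no ground truth for: {', '.join(missing[:10])}"
        )
    rng = np.random.default_rng(seed)
    records = []
    for lid in batch:
        mu = float(truth[lid])
        if cluster_bias is not None:
            mu += float(cluster_bias.get(lid, 0.0))
        reps = mu + sigma * rng.standard_normal(n_replicates)
        if n_replicates > 1:
            stderr = float(np.std(reps, ddof=1) / math.sqrt(n_replicates))
        else:
            stderr = 0.0
        records.append(
            AffinityRecord(
                ligand_id=lid,
                dg=float(np.mean(reps)),
                uncertainty=stderr,
                source="synthetic",
                n_replicates=n_replicates,
            )
        )
    return records


def rel_to_abs(
    ddg: float,
    reference_dg: float,
    ddg_err: float = 0.0,
    reference_err: float = 0.0,
) -> tuple[float, float]:
    """Combine a relative ΔΔG with the reference ligand's absolute ΔG.

    Returns (ΔG, uncertainty) with the two errors propagated in quadrature.
    """
    if not (np.isfinite(ddg) and np.isfinite(reference_dg)):
        raise ValueError("ddg and reference_dg must be finite")
    return float(reference_dg + ddg), float(math.hypot(ddg_err, reference_err))


class ManifestAdapter:
    """CSV bridge to an external free-energy engine.

    :meth:`write` emits a per-iteration manifest of ligands to evaluate
    relative to a reference ligand; :meth:`read` parses the engine's results
    (ligand_id, ddg, stderr) and converts them to absolute free energies.
    """

    def __init__(self, reference_id: str, reference_dg: float,
                 reference_err: float = 0.0):
        self.reference_id = reference_id
        self.reference_dg = float(reference_dg)
        self.reference_err = float(reference_err)

    def write(self, batch: Sequence[Ligand], iteration: int,
              path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["ligand_id", "smiles", "reference_id", "iteration"])
            for lig in batch:
                writer.writerow([lig.ligand_id, lig.smiles,
                                 self.reference_id, iteration])
        return path

    def read(
        self, path: str | Path, expected: Optional[Sequence[str]] = None
    ) -> tuple[list[AffinityRecord], list[str]]:
        """Parse results; returns (records, pending ligand ids).

        ``pending`` lists expected ligands absent from the results file, so a
        run can resume once the engine finishes them.
        """
        required = {"ligand_id", "ddg", "stderr"}
        records: list[AffinityRecord] = []
        seen: set[str] = set()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(
                    f"results file {path} must have columns {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            for rownum, row in enumerate(reader, start=2):
                try:
                    ddg = float(row["ddg"])
                    err = float(row["stderr"])
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"results file {path}, row {rownum}: "
                        f"unparseable ddg/stderr ({row})"
                    ) from exc
                dg, unc = rel_to_abs(ddg, self.reference_dg, err,
                                     self.reference_err)
                records.append(
                    AffinityRecord(
                        ligand_id=row["ligand_id"], dg=dg, uncertainty=unc,
                        source="computed",
                    )
                )
                seen.add(row["ligand_id"])
        pending = [] if expected is None else [l for l in expected if l not in seen]
        return records, pending
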