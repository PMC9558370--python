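"""Orchestration of the active-learning cycle and its evaluation metrics.

One cycle: an initial diversity-weighted random batch is evaluated by the
oracle; an ensemble is trained on everything evaluated so far and predicts
ΔG for the whole library; a selection strategy picks the next batch from
the unevaluated pool; the oracle evaluates it; repeat. The state is
checkpointed after every iteration and a run can resume from its
checkpoint; with fixed seeds the resumed run reproduces the uninterrupted
one, because all per-iteration seeds are derived deterministically from the
run seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import kendalltau

from .containers import AffinityRecord, FeatureBlock, SelectionBatch
from .ensemble import Ensemble, TrainHyper, predict, train_ensemble
from .oracle import lookup_oracle, synthetic_oracle
from . import selection as sel

logger = logging.getLogger(__name__)

__all__ = [
    "MetricRecord",
    "ALConfig",
    "ALState",
    "compute_metrics",
    "run_active_learning",
]


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricRecord:
    """Per-iteration evaluation against ground truth.

    ``top_n_recovered`` is the fraction of the library's true top-N binders
    already in the evaluated set; ``tpr`` is, among ligands truly at or
    below the ΔG threshold, the fraction also predicted at or below it
    (NaN when no ligand is truly below the threshold).
    """

    rmse: float
    kendall_tau: float
    top_n_recovered: float
    tpr: float
    n_evaluated: int


def compute_metrics(
    predictions: Mapping[str, float],
    truth: Mapping[str, float],
    evaluated_ids: Sequence[str],
    top_n: int = 50,
    tpr_threshold: float = -13.29,
) -> MetricRecord:
    """RMSE, Kendall τ, top-N recovery and TPR over the prediction ids."""
    ids = list(predictions)
    if not ids:
        raise ValueError("empty prediction set")
    missing = [i for i in ids if i not in truth]
    if missing:
        raise KeyError(f"truth missing for: {', '.join(missing[:10])}")
    pred = np.array([predictions[i] for i in ids])
    true = np.array([truth[i] for i in ids])
    rmse = float(np.sqrt(np.mean((pred - true) ** 2)))
    tau = float(kendalltau(pred, true).statistic) if len(ids) > 1 else 1.0

    top_ids = sorted(truth, key=lambda i: (truth[i], i))[:top_n]
    evaluated = set(evaluated_ids)
    recovered = sum(1 for i in top_ids if i in evaluated) / len(top_ids)

    truly_strong = true <= tpr_threshold
    if truly_strong.any():
        tpr = float((pred[truly_strong] <= tpr_threshold).mean())
    else:
        tpr = float("nan")
    return MetricRecord(
        rmse=rmse, kendall_tau=tau, top_n_recovered=float(recovered),
        tpr=tpr, n_evaluated=len(evaluated),
    )


# ---------------------------------------------------------------------------
# configuration and state


@dataclass
class ALConfig:
    """Everything one run needs, in memory.

    ``blocks`` are the candidate ligand representations; single-
    representation strategies use the first, the narrowing stage trains one
    model per block and ranks them by cross-validation RMSE.
    ``oracle_spec`` maps ligand ids to ground truth: ``{"kind": "lookup",
    "table": {id: (dg, err)}}`` or ``{"kind": "synthetic", "truth":
    {id: dg}, "sigma": 1.1, "n_replicates": 5}``.
    ``n_repeats`` may be an int or a per-iteration schedule
    ``{iteration: int}`` (missing iterations fall back to 1).
    """

    ligand_ids: list[str]
    blocks: list[FeatureBlock]
    oracle_spec: dict
    policy: str = "greedy"
    batch_size: int = 100
    max_iterations: int = 6
    switch_iteration: int = 3
    pool_factor: float = 3.0
    n_models: int = 5
    per_model_top: Optional[int] = None
    hyper: TrainHyper = field(default_factory=TrainHyper)
    k_folds: int = 5
    n_repeats: int | dict[int, int] = 1
    top_n: int = 50
    tpr_threshold: float = -13.29
    plateau_patience: Optional[int] = None
    embedding_block: Optional[FeatureBlock] = None
    embedding_coords: Optional[np.ndarray] = None
    embedding_perplexity: float = 30.0
    seed: int = 0
    checkpoint_dir: Optional[Path] = None

    def repeats_at(self, iteration: int) -> int:
        if isinstance(self.n_repeats, dict):
            return int(self.n_repeats.get(iteration, 1))
        return int(self.n_repeats)

    def truth(self) -> Optional[dict[str, float]]:
        spec = self.oracle_spec
        if spec["kind"] == "lookup":
            return {k: float(v[0]) for k, v in spec["table"].items()}
        if spec["kind"] == "synthetic":
            return {k: float(v) for k, v in spec["truth"].items()}
        return None

    def config_hash(self) -> str:
        payload = {
            "n_ligands": len(self.ligand_ids),
            "blocks": [b.name for b in self.blocks],
            "oracle_kind": self.oracle_spec.get("kind"),
            "policy": self.policy,
            "batch_size": self.batch_size,
            # max_iterations is a stopping rule, not part of the run identity:
            # a resumed run may extend it
            "switch_iteration": self.switch_iteration,
            "pool_factor": self.pool_factor,
            "hyper": dataclasses.asdict(self.hyper),
            "k_folds": self.k_folds,
            "n_repeats": self.n_repeats
            if isinstance(self.n_repeats, int)
            else sorted(self.n_repeats.items()),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ALState:
    """Iteration history of one active-learning run."""

    iteration: int = -1  # last completed iteration
    evaluated: dict[str, AffinityRecord] = field(default_factory=dict)
    batches: list[SelectionBatch] = field(default_factory=list)
    predictions_history: list[dict[str, tuple[float, float]]] = field(
        default_factory=list
    )
    metrics_history: list[Optional[MetricRecord]] = field(default_factory=list)
    config_hash: str = ""
    seed: int = 0
    best_dg_history: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "evaluated": {
                k: dataclasses.asdict(v) for k, v in self.evaluated.items()
            },
            "batches": [dataclasses.asdict(b) for b in self.batches],
            "predictions_history": [
                {k: list(v) for k, v in p.items()}
                for p in self.predictions_history
            ],
            "metrics_history": [
                None if m is None else dataclasses.asdict(m)
                for m in self.metrics_history
            ],
            "config_hash": self.config_hash,
            "seed": self.seed,
            "best_dg_history": self.best_dg_history,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ALState":
        return cls(
            iteration=d["iteration"],
            evaluated={
                k: AffinityRecord(**v) for k, v in d["evaluated"].items()
            },
            batches=[SelectionBatch(**b) for b in d["batches"]],
            predictions_history=[
                {k: (v[0], v[1]) for k, v in p.items()}
                for p in d["predictions_history"]
            ],
            metrics_history=[
                None if m is None else MetricRecord(**m)
                for m in d["metrics_history"]
            ],
            config_hash=d["config_hash"],
            seed=d["seed"],
            best_dg_history=list(d["best_dg_history"]),
        )

    def save(self, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.to_dict()))
        tmp.replace(path)

    @classmethod
    def load(cls, path: Path) -> "ALState":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# run driver


def _derive_seed(root: int, *tags: int) -> int:
    return int(
        np.random.SeedSequence([root, *tags]).generate_state(1)[0] % (2 ** 31)
    )


def _make_oracle(spec: dict, run_seed: int) -> Callable[
    [Sequence[str], int], list[AffinityRecord]
]:
    kind = spec.get("kind")
    if kind == "lookup":
        table = spec["table"]
        return lambda batch, iteration: lookup_oracle(batch, table)
    if kind == "synthetic":
        truth = spec["truth"]
        sigma = float(spec.get("sigma", 1.1))
        n_rep = int(spec.get("n_replicates", 5))
        return lambda batch, iteration: synthetic_oracle(
            batch, truth, sigma=sigma, n_replicates=n_rep,
            seed=_derive_seed(run_seed, 101, iteration),
        )
    if kind == "callable":
        return spec["fn"]
    raise ValueError(f"unknown oracle kind {kind!r}")


def _get_embedding(config: ALConfig) -> np.ndarray:
    if config.embedding_coords is not None:
        return np.asarray(config.embedding_coords, dtype=float)
    block = config.embedding_block or config.blocks[0]
    cache = None
    if config.checkpoint_dir is not None:
        cache = Path(config.checkpoint_dir) / "embedding.npy"
        if cache.exists():
            return np.load(cache)
    coords = sel.compute_embedding(
        block, seed=_derive_seed(config.seed, 11),
        perplexity=config.embedding_perplexity,
    )
    if cache is not None:
        cache.parent.mkdir(parents=True, exist_ok=True)
        np.save(cache, coords)
    return coords


def _train_models(
    config: ALConfig, state: ALState, iteration: int, multi: bool
) -> tuple[dict[str, Ensemble], str]:
    """Train ensembles on the evaluated set; returns (by-block map, name of
    the primary model — the one with the lowest cv RMSE)."""
    records = list(state.evaluated.values())
    blocks = config.blocks if multi else config.blocks[:1]
    ensembles: dict[str, Ensemble] = {}
    for bi, block in enumerate(blocks):
        hyper = dataclasses.replace(
            config.hyper, seed=_derive_seed(config.seed, 23, iteration, bi)
        )
        ensembles[block.name] = train_ensemble(
            [block], records, hyper=hyper, k_folds=config.k_folds,
            n_repeats=config.repeats_at(iteration),
        )
    primary = min(ensembles, key=lambda n: (ensembles[n].cv_rmse, n))
    return ensembles, primary


def _predict_library(
    config: ALConfig, ensembles: dict[str, Ensemble]
) -> dict[str, dict[str, tuple[float, float]]]:
    by_name = {b.name: b for b in config.blocks}
    out = {}
    for name, ens in ensembles.items():
        preds = predict(ens, [by_name[name]], config.ligand_ids)
        out[name] = {p.ligand_id: (p.mean_dg, p.stderr_dg) for p in preds}
    return out


def _select(
    config: ALConfig,
    state: ALState,
    iteration: int,
    predictions_by_model: dict[str, dict[str, tuple[float, float]]],
    cv_rmse_by_model: dict[str, float],
    primary: str,
) -> SelectionBatch:
    strategy = sel.policy_schedule(iteration, config.policy,
                                   config.switch_iteration)
    excluded = set(state.evaluated)
    preds = predictions_by_model[primary]
    if strategy == "random":
        batch = sel.select_random(
            config.ligand_ids, excluded, config.batch_size,
            seed=_derive_seed(config.seed, 37, iteration),
            iteration=iteration,
        )
    elif strategy == "greedy":
        batch = sel.select_greedy(preds, excluded, config.batch_size,
                                  iteration=iteration)
    elif strategy == "uncertain":
        batch = sel.select_uncertain(preds, excluded, config.batch_size,
                                     iteration=iteration)
    elif strategy == "mixed":
        batch = sel.select_mixed(preds, excluded, config.batch_size,
                                 pool_factor=config.pool_factor,
                                 iteration=iteration)
    elif strategy == "narrowing_multi":
        n_models = min(config.n_models, len(predictions_by_model))
        per_top = config.per_model_top or max(
            1, config.batch_size // n_models
        )
        batch = sel.select_narrowing(
            predictions_by_model, cv_rmse_by_model, excluded,
            batch_size=config.batch_size, n_models=n_models,
            per_model_top=per_top, iteration=iteration,
        )
    else:  # pragma: no cover - guarded by policy_schedule
        raise ValueError(f"unhandled strategy {strategy!r}")
    overlap = set(batch.ligand_ids) & excluded
    assert not overlap, f"strategy re-selected evaluated ligands: {overlap}"
    return batch


def _post_batch(
    config: ALConfig, state: ALState, iteration: int, truth: Optional[dict]
) -> tuple[dict[str, dict[str, tuple[float, float]]], dict[str, float], str]:
    """Train, predict the library, and record metrics after a new batch."""
    next_strategy = sel.policy_schedule(
        iteration + 1, config.policy, config.switch_iteration
    )
    multi = next_strategy == "narrowing_multi" and len(config.blocks) > 1
    ensembles, primary = _train_models(config, state, iteration, multi)
    predictions_by_model = _predict_library(config, ensembles)
    cv_rmse = {n: e.cv_rmse for n, e in ensembles.items()}
    state.predictions_history.append(predictions_by_model[primary])
    if truth is not None:
        mean_preds = {
            k: v[0] for k, v in predictions_by_model[primary].items()
        }
        state.metrics_history.append(
            compute_metrics(mean_preds, truth, list(state.evaluated),
                            top_n=config.top_n,
                            tpr_threshold=config.tpr_threshold)
        )
    else:
        state.metrics_history.append(None)
    state.best_dg_history.append(
        min(r.dg for r in state.evaluated.values())
    )
    return predictions_by_model, cv_rmse, primary


def run_active_learning(
    config: ALConfig, resume: bool = False
) -> ALState:
    """Run (or resume) the full cycle; returns the final state.

    Iteration 0 evaluates the diversity-weighted random batch, then trains
    and predicts; iterations 1..max_iterations select with the policy's
    strategy, evaluate, retrain and re-predict. With ``plateau_patience``
    set, the run halts early once the best ΔG found has not improved for
    that many consecutive iterations.
    """
    ckpt = None
    if config.checkpoint_dir is not None:
        config.checkpoint_dir = Path(config.checkpoint_dir)
        ckpt = config.checkpoint_dir / "state.json"
    oracle = _make_oracle(config.oracle_spec, config.seed)
    truth = config.truth()

    if resume:
        if ckpt is None or not ckpt.exists():
            raise FileNotFoundError("no checkpoint to resume from")
        state = ALState.load(ckpt)
        if state.config_hash != config.config_hash():
            raise ValueError("checkpoint was produced under a different config")
        logger.info("resuming at iteration %d", state.iteration + 1)
        preds_by_model, cv_rmse, primary = _post_batch_replay(
            config, state, truth
        )
    else:
        state = ALState(seed=config.seed, config_hash=config.config_hash())
        coords = _get_embedding(config)
        batch = sel.weighted_random_init(
            config.ligand_ids, coords, config.batch_size,
            seed=_derive_seed(config.seed, 37, 0),
        )
        _evaluate(state, batch, oracle)
        preds_by_model, cv_rmse, primary = _post_batch(config, state, 0, truth)
        state.iteration = 0
        if ckpt is not None:
            state.save(ckpt)

    stall = 0
    for iteration in range(state.iteration + 1, config.max_iterations + 1):
        batch = _select(config, state, iteration, preds_by_model, cv_rmse,
                        primary)
        if not batch.ligand_ids:
            logger.warning("candidate pool empty; stopping early")
            break
        try:
            _evaluate(state, batch, oracle)
        except Exception:
            if ckpt is not None:
                state.save(ckpt)
            logger.exception("oracle failed; state checkpointed for resume")
            raise
        preds_by_model, cv_rmse, primary = _post_batch(
            config, state, iteration, truth
        )
        state.iteration = iteration
        if ckpt is not None:
            state.save(ckpt)
        if config.plateau_patience is not None and len(
            state.best_dg_history
        ) >= 2:
            if state.best_dg_history[-1] >= state.best_dg_history[-2] - 1e-9:
                stall += 1
            else:
                stall = 0
            if stall >= config.plateau_patience:
                logger.info(
                    "best ΔG plateaued for %d iterations; halting", stall
                )
                break
    return state


def _post_batch_replay(config, state, truth):
    """Recreate the training/prediction products of the last completed
    iteration without touching the recorded history (used on resume)."""
    saved_preds = state.predictions_history
    saved_metrics = state.metrics_history
    saved_best = state.best_dg_history
    state.predictions_history = []
    state.metrics_history = []
    state.best_dg_history = []
    out = _post_batch(config, state, state.iteration, truth)
    state.predictions_history = saved_preds
    state.metrics_history = saved_metrics
    state.best_dg_history = saved_best
    return out


def _evaluate(state: ALState, batch: SelectionBatch, oracle) -> None:
    records = oracle(batch.ligand_ids, batch.iteration)
    for rec in records:
        if rec.ligand_id in state.evaluated:
            raise ValueError(
                f"ligand {rec.ligand_id} evaluated twice"
            )
        state.evaluated[rec.ligand_id] = rec
    state.batches.append(batch)
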