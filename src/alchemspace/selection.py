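"""Batch-selection strategies for the active-learning cycle.

All strategies return a :class:`SelectionBatch` of ligands disjoint from
everything already evaluated, of the requested size unless the candidate
pool runs out. Ties are always broken lexicographically by ligand id, so
every strategy is deterministic given the prediction table (plus the seed,
for the stochastic ones).

Strategies:

* ``random`` — uniform sampling of unevaluated ligands;
* ``greedy`` — the strongest predicted binders (most negative mean ΔG);
* ``uncertain`` — the largest prediction uncertainties;
* ``mixed`` — the most uncertain among a pool of the top
  ``pool_factor × batch_size`` predicted binders (1:1 ratio reduces to
  greedy; a pool covering all candidates reduces to uncertain);
* ``narrowing`` — in early iterations, the top binders of the best few
  models trained on different ligand representations (ranked by
  cross-validation RMSE), later switching to greedy.

Initialization (iteration 0) uses diversity-weighted random selection:
ligands are drawn with probability inversely proportional to how many
library members share their bin of a 2-D stochastic-neighbor embedding.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np

from .containers import FeatureBlock, SelectionBatch

logger = logging.getLogger(__name__)

__all__ = [
    "compute_embedding",
    "bin_embedding",
    "weighted_random_init",
    "select_random",
    "select_greedy",
    "select_uncertain",
    "select_mixed",
    "select_narrowing",
    "policy_schedule",
]


# ---------------------------------------------------------------------------
# prediction-table helpers


def _candidates(
    predictions: Mapping[str, tuple[float, float]],
    excluded: set[str],
) -> list[str]:
    return [lid for lid in predictions if lid not in excluded]


def _take_top(
    ids: Sequence[str],
    key: Mapping[str, float],
    n: int,
    largest: bool,
) -> list[str]:
    """Top-n ids by ``key``; ties broken lexicographically by ligand id."""
    sign = -1.0 if largest else 1.0
    return sorted(ids, key=lambda lid: (sign * key[lid], lid))[:n]


def _warn_short(strategy: str, got: int, wanted: int) -> None:
    if got < wanted:
        logger.warning("%s: candidate pool exhausted, batch of %d < %d",
                       strategy, got, wanted)


# ---------------------------------------------------------------------------
# diversity-weighted initialization


def compute_embedding(
    block: FeatureBlock, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2-D t-SNE embedding of a feature block (one row per ligand).

    Stochastic-neighbor embeddings vary run to run, so callers should cache
    the returned coordinates (the run driver stores them in the checkpoint
    directory) and reuse them for binning.
    """
    from sklearn.manifold import TSNE

    perplexity = min(perplexity, max(1.0, (block.n_ligands - 1) / 3.0))
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return np.asarray(tsne.fit_transform(block.matrix), dtype=float)


def bin_embedding(coords: np.ndarray, bin_side: float = 1.0) -> np.ndarray:
    """Integer (i, j) bin per ligand on a square grid of side ``bin_side``."""
    if bin_side <= 0:
        raise ValueError("bin_side must be positive")
    return np.floor(np.asarray(coords, dtype=float) / bin_side).astype(int)


def weighted_random_init(
    ligand_ids: Sequence[str],
    embedding_coords: np.ndarray,
    batch_size: int,
    seed: int = 0,
    bin_side: float = 1.0,
) -> SelectionBatch:
    """Initial batch drawn with probability ∝ 1 / (ligands in same bin).

    Ligands are considered similar when they fall in the same unit-square
    bin of the 2-D embedding; down-weighting crowded bins spreads the
    initial training set across chemical space.
    """
    if len(ligand_ids) < batch_size:
        raise ValueError(
            f"library of {len(ligand_ids)} cannot fill a batch of {batch_size}"
        )
    coords = np.asarray(embedding_coords, dtype=float)
    if coords.shape != (len(ligand_ids), 2):
        raise ValueError("embedding_coords must be (n_ligands, 2)")
    bins = bin_embedding(coords, bin_side)
    keys = [tuple(b) for b in bins]
    counts: dict[tuple[int, int], int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    weights = np.array([1.0 / counts[k] for k in keys])
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ligand_ids), size=batch_size, replace=False,
                        p=weights)
    ids = [ligand_ids[i] for i in chosen]
    return SelectionBatch(
        iteration=0, strategy="weighted_random_init", ligand_ids=ids,
        rationale=[f"bin={keys[i]}" for i in chosen],
    )


# ---------------------------------------------------------------------------
# per-iteration strategies


def select_random(
    ligand_ids: Sequence[str],
    excluded: set[str],
    batch_size: int,
    seed: int = 0,
    iteration: int = 0,
) -> SelectionBatch:
    """Uniform sampling without replacement from the unevaluated pool."""
    pool = sorted(lid for lid in ligand_ids if lid not in excluded)
    n = min(batch_size, len(pool))
    _warn_short("random", n, batch_size)
    rng = np.random.default_rng(seed)
    ids = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
    return SelectionBatch(iteration=iteration, strategy="random",
                          ligand_ids=ids,
                          rationale=["uniform"] * n)


def select_greedy(
    predictions: Mapping[str, tuple[float, float]],
    excluded: set[str],
    batch_size: int,
    iteration: int = 0,
) -> SelectionBatch:
    """The ``batch_size`` ligands with the most negative predicted ΔG."""
    pool = _candidates(predictions, excluded)
    mean_dg = {lid: predictions[lid][0] for lid in pool}
    ids = _take_top(pool, mean_dg, batch_size, largest=False)
    _warn_short("greedy", len(ids), batch_size)
    return SelectionBatch(
        iteration=iteration, strategy="greedy", ligand_ids=ids,
        rationale=[f"pred_dg={mean_dg[lid]:.3f}" for lid in ids],
    )


def select_uncertain(
    predictions: Mapping[str, tuple[float, float]],
    excluded: set[str],
    batch_size: int,
    iteration: int = 0,
) -> SelectionBatch:
    """The ``batch_size`` ligands with the largest prediction uncertainty."""
    pool = _candidates(predictions, excluded)
    unc = {lid: predictions[lid][1] for lid in pool}
    ids = _take_top(pool, unc, batch_size, largest=True)
    _warn_short("uncertain", len(ids), batch_size)
    return SelectionBatch(
        iteration=iteration, strategy="uncertain", ligand_ids=ids,
        rationale=[f"unc={unc[lid]:.3f}" for lid in ids],
    )


def select_mixed(
    predictions: Mapping[str, tuple[float, float]],
    excluded: set[str],
    batch_size: int,
    pool_factor: float = 3.0,
    iteration: int = 0,
) -> SelectionBatch:
    """Most uncertain among the top ``pool_factor × batch_size`` binders.

    With a 1:1 ratio the pool is exactly the greedy batch; with a pool
    covering every candidate this reduces to uncertainty selection.
    """
    if pool_factor < 1:
        raise ValueError("pool_factor must be >= 1")
    cand = _candidates(predictions, excluded)
    mean_dg = {lid: predictions[lid][0] for lid in cand}
    unc = {lid: predictions[lid][1] for lid in cand}
    pool = _take_top(cand, mean_dg, int(round(pool_factor * batch_size)),
                     largest=False)
    ids = _take_top(pool, unc, batch_size, largest=True)
    _warn_short("mixed", len(ids), batch_size)
    return SelectionBatch(
        iteration=iteration, strategy="mixed", ligand_ids=ids,
        rationale=[f"pred_dg={mean_dg[lid]:.3f};unc={unc[lid]:.3f}"
                   for lid in ids],
    )


def select_narrowing(
    predictions_by_model: Mapping[str, Mapping[str, tuple[float, float]]],
    cv_rmse_by_model: Mapping[str, float],
    excluded: set[str],
    batch_size: int = 100,
    n_models: int = 5,
    per_model_top: int = 20,
    iteration: int = 0,
) -> SelectionBatch:
    """Broad multi-representation selection for the early iterations.

    The ``n_models`` models with the lowest cross-validation RMSE each
    nominate their best predicted binders. When models nominate the same
    ligand, the duplicate is replaced by that model's next-best candidate:
    models take turns in cv-RMSE order (round-robin), each contributing its
    next-best unclaimed ligand, until ``n_models × per_model_top`` unique
    ligands (= ``batch_size`` with the defaults) are collected.
    """
    if len(predictions_by_model) < n_models:
        raise ValueError(
            f"narrowing needs {n_models} models, got "
            f"{len(predictions_by_model)}"
        )
    target = min(batch_size, n_models * per_model_top)
    ranked_models = sorted(cv_rmse_by_model,
                           key=lambda m: (cv_rmse_by_model[m], m))[:n_models]
    queues = {}
    for m in ranked_models:
        preds = predictions_by_model[m]
        cand = _candidates(preds, excluded)
        queues[m] = _take_top(cand, {l: preds[l][0] for l in cand},
                              len(cand), largest=False)
    cursors = {m: 0 for m in ranked_models}
    chosen: list[str] = []
    rationale: list[str] = []
    claimed: set[str] = set()
    progress = True
    while len(chosen) < target and progress:
        progress = False
        for m in ranked_models:
            if len(chosen) >= target:
                break
            q = queues[m]
            c = cursors[m]
            while c < len(q) and q[c] in claimed:
                c += 1
            cursors[m] = c
            if c < len(q):
                chosen.append(q[c])
                rationale.append(f"model={m};rank={c + 1}")
                claimed.add(q[c])
                cursors[m] = c + 1
                progress = True
    _warn_short("narrowing", len(chosen), target)
    return SelectionBatch(
        iteration=iteration, strategy="narrowing", ligand_ids=chosen,
        rationale=rationale,
    )


# ---------------------------------------------------------------------------
# policies


def policy_schedule(iteration: int, policy_name: str,
                    switch_iteration: int = 3) -> str:
    """Map (policy, iteration) to the concrete strategy for that iteration.

    Iteration 0 is always the diversity-weighted random initialization.
    ``narrowing`` uses multi-representation selection for the first
    ``switch_iteration`` selection rounds and greedy afterwards;
    ``random2greedy`` does the same with random in place of the
    multi-representation stage.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if iteration == 0:
        return "weighted_random_init"
    simple = {"random", "greedy", "uncertain", "mixed"}
    if policy_name in simple:
        return policy_name
    if policy_name == "narrowing":
        return "narrowing_multi" if iteration <= switch_iteration else "greedy"
    if policy_name == "random2greedy":
        return "random" if iteration <= switch_iteration else "greedy"
    raise ValueError(f"unknown policy {policy_name!r}")
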