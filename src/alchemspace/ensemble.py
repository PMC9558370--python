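"""Cross-validation ensembles of multilayer perceptrons for ΔG regression.

Each ensemble member is a small fully connected network with ReLU hidden
layers and a linear output, trained with an inverse-frequency-weighted L1
loss, plain SGD with momentum, an exponentially decaying learning rate, and
early stopping on its held-out fold. Members come from a k-fold split of
the training data (one member per fold, each leaving that fold out), and
the split is repeated ``n_repeats`` times with fresh shuffles, so the
ensemble holds k × n_repeats members. The ensemble prediction is the
arithmetic mean over members; the spread over members (standard error by
default, standard deviation optionally) serves as the prediction
uncertainty consumed by the selection strategies.

The implementation is pure NumPy and, with a fixed seed, bit-reproducible
in single-threaded execution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .containers import AffinityRecord, FeatureBlock

__all__ = [
    "TrainHyper",
    "Ensemble",
    "EnsemblePrediction",
    "inverse_frequency_weights",
    "lr_schedule",
    "train_ensemble",
    "predict",
    "importance_filter",
    "integrated_gradients",
]


def lr_schedule(epoch: int, lr0: float = 0.005,
                decay_per: float = 10000.0) -> float:
    """Exponentially decaying learning rate: lr0 · 0.1^(epoch / decay_per)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return lr0 * 0.1 ** (epoch / decay_per)


def inverse_frequency_weights(
    targets: Sequence[float], bandwidth: Optional[float] = None
) -> np.ndarray:
    """Per-example loss weights ∝ 1 / KDE(target), mean-normalized to 1.

    A Gaussian kernel density estimate of the training free energies is
    evaluated at each target; rare affinity ranges get up-weighted so the
    loss is not dominated by the heavily sampled medium-affinity region.
    ``bandwidth`` is an absolute kernel width in kcal/mol; the default is
    Scott's rule. Degenerate inputs (all targets equal) get uniform weights.
    """
    t = np.asarray(targets, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two targets for density weighting")
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    std = t.std(ddof=1)
    if std == 0:
        return np.ones_like(t)
    bw_method = None if bandwidth is None else bandwidth / std
    kde = gaussian_kde(t, bw_method=bw_method)
    density = kde(t)
    w = 1.0 / density
    return w / w.mean()


@dataclass
class TrainHyper:
    """Training protocol knobs (free energies in kcal/mol).

    ``target_scale``/``target_bias`` define the affine transform applied to
    targets before fitting, t = (ΔG − bias) / scale; predictions are always
    reported back in kcal/mol. ``early_stop_patience`` defaults to 10% of
    ``epochs``; best-so-far weights are checkpointed and restored.
    """

    hidden_layer_widths: tuple[int, ...] = (64, 32)
    epochs: int = 2000
    lr0: float = 0.005
    lr_decay_per: float = 10000.0
    momentum: float = 0.9
    batch_cap: int = 500
    target_scale: float = 3.0
    target_bias: float = -10.0
    early_stop_patience: Optional[int] = None
    kde_bandwidth: Optional[float] = None
    uncertainty: str = "stderr"  # stderr | std
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.batch_cap < 1:
            raise ValueError("batch_cap must be >= 1")
        if self.target_scale == 0:
            raise ValueError("target_scale must be nonzero")
        if self.uncertainty not in ("stderr", "std"):
            raise ValueError("uncertainty must be 'stderr' or 'std'")

    @property
    def patience(self) -> int:
        if self.early_stop_patience is not None:
            return self.early_stop_patience
        return max(1, self.epochs // 10)


class _MLP:
    """Minimal fully connected ReLU network with a scalar linear output."""

    def __init__(self, d_in: int, hidden: Sequence[int],
                 rng: np.random.Generator):
        widths = [d_in, *hidden, 1]
        self.W = []
        self.b = []
        n_layers = len(widths) - 1
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            # He initialization for the ReLU layers; the output layer starts
            # small so the initial function is nearly flat and complexity is
            # grown by the optimizer rather than baked in at random
            scale = math.sqrt(2.0 / a)
            if i == n_layers - 1 and n_layers > 1:
                scale *= 0.1
            self.W.append(rng.standard_normal((a, b)) * scale)
            self.b.append(np.zeros(b))

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return h[:, 0], acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def input_gradients(self, X: np.ndarray) -> np.ndarray:
        """∂output/∂input per sample (exact, via backprop)."""
        _, acts = self.forward(X)
        g = np.ones((X.shape[0], 1))
        for i in range(len(self.W) - 1, -1, -1):
            g = g @ self.W[i].T
            if i > 0:
                g = g * (acts[i] > 0)
        return g

    def _backward(self, acts: list[np.ndarray],
                  dloss_dout: np.ndarray) -> tuple[list, list]:
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dloss_dout[:, None]
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        return gW, gb

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for p in (*self.W, *self.b)]

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]

    def fit(
        self,
        X: np.ndarray,
        t: np.ndarray,
        sample_weights: np.ndarray,
        X_val: np.ndarray,
        t_val: np.ndarray,
        hyper: TrainHyper,
        rng: np.random.Generator,
    ) -> float:
        """Weighted-L1 SGD training with early stopping on validation L1.

        Returns the best validation loss; the network is left at the
        checkpointed best weights.
        """
        n = X.shape[0]
        vW = [np.zeros_like(W) for W in self.W]
        vb = [np.zeros_like(b) for b in self.b]
        best_val = math.inf
        best_params = self.get_params()
        stall = 0
        for epoch in range(hyper.epochs):
            lr = lr_schedule(epoch, hyper.lr0, hyper.lr_decay_per)
            order = rng.permutation(n)
            for start in range(0, n, hyper.batch_cap):
                sel = order[start:start + hyper.batch_cap]
                out, acts = self.forward(X[sel])
                resid = out - t[sel]
                if not np.isfinite(resid).all():
                    raise FloatingPointError("non-finite training loss")
                dloss = sample_weights[sel] * np.sign(resid) / sel.size
                gW, gb = self._backward(acts, dloss)
                for i in range(len(self.W)):
                    vW[i] = hyper.momentum * vW[i] - lr * gW[i]
                    vb[i] = hyper.momentum * vb[i] - lr * gb[i]
                    self.W[i] += vW[i]
                    self.b[i] += vb[i]
            val_loss = float(np.mean(np.abs(self.predict(X_val) - t_val)))
            if not math.isfinite(val_loss):
                raise FloatingPointError("non-finite validation loss")
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = self.get_params()
                stall = 0
            else:
                stall += 1
                if stall >= hyper.patience:
                    break
        self.set_params(best_params)
        return best_val


@dataclass
class _Member:
    net: _MLP
    fold: int
    repeat: int


@dataclass
class Ensemble:
    """A trained cross-validation ensemble plus its input-space transform."""

    members: list[_Member]
    fold_assignments: dict[int, np.ndarray]  # repeat -> fold label per ligand
    training_ids: list[str]
    cv_rmse: float
    feature_block_names: list[str]
    feature_names: list[str]
    feature_means: np.ndarray
    feature_stds: np.ndarray
    hyper: TrainHyper
    n_aborted: int = 0

    @property
    def k_folds(self) -> int:
        return int(max(m.fold for m in self.members) + 1)

    @property
    def n_repeats(self) -> int:
        return int(max(m.repeat for m in self.members) + 1)

    def save(self, path) -> None:
        """Serialize the trained ensemble (weights + config) as JSON."""
        import dataclasses
        import json
        from pathlib import Path

        payload = {
            "format_version": 1,
            "hyper": dataclasses.asdict(self.hyper),
            "cv_rmse": self.cv_rmse,
            "n_aborted": self.n_aborted,
            "training_ids": self.training_ids,
            "feature_block_names": self.feature_block_names,
            "feature_names": self.feature_names,
            "feature_means": self.feature_means.tolist(),
            "feature_stds": self.feature_stds.tolist(),
            "fold_assignments": {
                str(k): v.tolist() for k, v in self.fold_assignments.items()
            },
            "members": [
                {
                    "fold": m.fold,
                    "repeat": m.repeat,
                    "W": [w.tolist() for w in m.net.W],
                    "b": [b.tolist() for b in m.net.b],
                }
                for m in self.members
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "Ensemble":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != 1:
            raise ValueError(
                f"unsupported checkpoint format: "
                f"{payload.get('format_version')!r}"
            )
        hyper = TrainHyper(**{
            **payload["hyper"],
            "hidden_layer_widths": tuple(
                payload["hyper"]["hidden_layer_widths"]
            ),
        })
        members = []
        for m in payload["members"]:
            net = _MLP.__new__(_MLP)
            net.W = [np.asarray(w, dtype=float) for w in m["W"]]
            net.b = [np.asarray(b, dtype=float) for b in m["b"]]
            members.append(_Member(net=net, fold=m["fold"],
                                   repeat=m["repeat"]))
        return cls(
            members=members,
            fold_assignments={
                int(k): np.asarray(v, dtype=int)
                for k, v in payload["fold_assignments"].items()
            },
            training_ids=payload["training_ids"],
            cv_rmse=payload["cv_rmse"],
            feature_block_names=payload["feature_block_names"],
            feature_names=payload["feature_names"],
            feature_means=np.asarray(payload["feature_means"], dtype=float),
            feature_stds=np.asarray(payload["feature_stds"], dtype=float),
            hyper=hyper,
            n_aborted=payload["n_aborted"],
        )

    def design_matrix(self, blocks: Sequence[FeatureBlock],
                      ligand_ids: Sequence[str]) -> np.ndarray:
        """Concatenate and standardize block rows for the given ligands."""
        by_name = {b.name: b for b in blocks}
        missing = [n for n in self.feature_block_names if n not in by_name]
        if missing:
            raise KeyError(f"feature blocks missing: {', '.join(missing)}")
        X = np.hstack([
            by_name[n].rows(ligand_ids) for n in self.feature_block_names
        ])
        return (X - self.feature_means) / self.feature_stds


@dataclass
class EnsemblePrediction:
    ligand_id: str
    mean_dg: float
    stderr_dg: float
    member_values: list[float] = field(default_factory=list)


def _concat_blocks(
    blocks: Sequence[FeatureBlock], ligand_ids: Sequence[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    X = np.hstack([b.rows(ligand_ids) for b in blocks])
    names = [f"{b.name}::{f}" for b in blocks for f in b.feature_names]
    return X, names, [b.name for b in blocks]


def train_ensemble(
    blocks: Sequence[FeatureBlock],
    records: Sequence[AffinityRecord],
    hyper: Optional[TrainHyper] = None,
    k_folds: int = 5,
    n_repeats: int = 1,
) -> Ensemble:
    """Train a k-fold × n_repeats ensemble on the evaluated ligands.

    Feature standardization and the inverse-frequency loss weights are
    fitted on training data only: the scaler on all training records, the
    weights per member on its own k−1 training folds. ``cv_rmse`` pools
    every member's held-out-fold predictions (in kcal/mol), the statistic
    the narrowing strategy ranks representations by.

    A member whose loss turns non-finite is aborted; the ensemble fails if
    more than half its members abort.
    """
    if hyper is None:
        hyper = TrainHyper()
    ids = [r.ligand_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ligand ids in training records")
    if len(ids) < k_folds:
        raise ValueError(
            f"{len(ids)} training records cannot fill {k_folds} folds"
        )
    y = np.array([r.dg for r in records], dtype=float)
    X_raw, feat_names, block_names = _concat_blocks(blocks, ids)

    means = X_raw.mean(axis=0)
    stds = X_raw.std(axis=0)
    # numerically constant columns: std at rounding-noise level
    constant = stds <= 1e-12 * np.maximum(1.0, np.abs(means))
    stds = np.where(constant, 1.0, stds)
    X = (X_raw - means) / stds
    t_all = (y - hyper.target_bias) / hyper.target_scale

    seed_root = np.random.SeedSequence(hyper.seed)
    split_seeds = seed_root.spawn(n_repeats)
    members: list[_Member] = []
    fold_assignments: dict[int, np.ndarray] = {}
    held_pred: list[np.ndarray] = []
    held_true: list[np.ndarray] = []
    n_aborted = 0
    for rep in range(n_repeats):
        rng_split = np.random.default_rng(split_seeds[rep])
        order = rng_split.permutation(len(ids))
        labels = np.empty(len(ids), dtype=int)
        for f, chunk in enumerate(np.array_split(order, k_folds)):
            labels[chunk] = f
        fold_assignments[rep] = labels
        member_seeds = split_seeds[rep].spawn(k_folds)
        for f in range(k_folds):
            train_mask = labels != f
            w = inverse_frequency_weights(y[train_mask], hyper.kde_bandwidth)
            rng = np.random.default_rng(member_seeds[f])
            net = _MLP(X.shape[1], hyper.hidden_layer_widths, rng)
            try:
                net.fit(X[train_mask], t_all[train_mask], w,
                        X[~train_mask], t_all[~train_mask], hyper, rng)
            except FloatingPointError:
                n_aborted += 1
                continue
            members.append(_Member(net=net, fold=f, repeat=rep))
            held_pred.append(
                net.predict(X[~train_mask]) * hyper.target_scale
                + hyper.target_bias
            )
            held_true.append(y[~train_mask])
    if n_aborted > (k_folds * n_repeats) // 2:
        raise RuntimeError(
            f"ensemble training failed: {n_aborted} of "
            f"{k_folds * n_repeats} members aborted with non-finite loss"
        )
    pooled_err = np.concatenate(held_pred) - np.concatenate(held_true)
    return Ensemble(
        members=members,
        fold_assignments=fold_assignments,
        training_ids=list(ids),
        cv_rmse=float(np.sqrt(np.mean(pooled_err ** 2))),
        feature_block_names=block_names,
        feature_names=feat_names,
        feature_means=means,
        feature_stds=stds,
        hyper=hyper,
        n_aborted=n_aborted,
    )


def predict(
    ensemble: Ensemble,
    blocks: Sequence[FeatureBlock],
    ligand_ids: Sequence[str],
) -> list[EnsemblePrediction]:
    """Mean and spread of member predictions, reported in kcal/mol."""
    X = ensemble.design_matrix(blocks, ligand_ids)
    hyper = ensemble.hyper
    member_out = np.stack([
        m.net.predict(X) * hyper.target_scale + hyper.target_bias
        for m in ensemble.members
    ])  # (n_members, n_ligands)
    mean = member_out.mean(axis=0)
    n_members = member_out.shape[0]
    if n_members > 1:
        spread = member_out.std(axis=0, ddof=1)
        if hyper.uncertainty == "stderr":
            spread = spread / math.sqrt(n_members)
    else:
        spread = np.zeros_like(mean)
    return [
        EnsemblePrediction(
            ligand_id=lid,
            mean_dg=float(mean[i]),
            stderr_dg=float(spread[i]),
            member_values=[float(v) for v in member_out[:, i]],
        )
        for i, lid in enumerate(ligand_ids)
    ]


def integrated_gradients(
    net: _MLP,
    X: np.ndarray,
    baseline: Optional[np.ndarray] = None,
    m_steps: int = 256,
) -> np.ndarray:
    """Integrated-Gradients attributions for each sample in ``X``.

    The path integral of the input gradient from ``baseline`` (default: the
    all-zeros vector, i.e. the mean ligand in standardized feature space) to
    each input is approximated by an m-step right Riemann sum:
    (x − b) · (1/m) Σ_k ∇f(b + (k/m)(x − b)).
    """
    if m_steps < 1:
        raise ValueError("m_steps must be >= 1")
    if baseline is None:
        baseline = np.zeros(X.shape[1])
    diff = X - baseline
    total = np.zeros_like(X, dtype=float)
    for k in range(1, m_steps + 1):
        point = baseline + (k / m_steps) * diff
        total += net.input_gradients(point)
    return diff * total / m_steps


def importance_filter(
    ensemble: Ensemble,
    blocks: Sequence[FeatureBlock],
    threshold: float = 0.02,
    probe_ids: Optional[Sequence[str]] = None,
    m_steps: int = 256,
) -> list[str]:
    """Keep features whose mean |IG| attribution reaches ``threshold``.

    Importance is the absolute Integrated-Gradients attribution averaged
    over ensemble members and a probe set (default: the training ligands).
    A constant feature has zero attribution everywhere and is dropped at
    any positive threshold. Raises if nothing survives.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if probe_ids is None:
        probe_ids = ensemble.training_ids
    X = ensemble.design_matrix(blocks, probe_ids)
    importance = np.zeros(X.shape[1])
    for m in ensemble.members:
        importance += np.abs(
            integrated_gradients(m.net, X, m_steps=m_steps)
        ).mean(axis=0)
    importance /= len(ensemble.members)
    keep = [
        name for name, imp in zip(ensemble.feature_names, importance)
        if imp >= threshold
    ]
    if not keep:
        raise ValueError(
            f"importance threshold {threshold} drops every feature; "
            "lower the threshold"
        )
    return keep
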