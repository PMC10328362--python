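"""Cohort splitting, mini-batch training with per-epoch checkpointing,
validation-based checkpoint selection, and benchmarking metrics.

The benchmarking conventions: ROC AUC via the rank statistic (mid-rank tie
handling), PR AUC via average precision (step interpolation), baselines of
0.5 for ROC and the trait prevalence for PR, and the transfer statistic

    relative increase = ((model - baseline) - (stl - baseline))
                        / (stl - baseline) * 100%

quantifying a model's over-baseline AUC gain relative to the single-task
baseline's gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .genio import GenotypeDataset, PhenotypeMatrix
from .linamodel import MTLModel, STLModel, load_checkpoint, make_optimizer, save_checkpoint


@dataclass
class SplitSpec:
    """Disjoint subject-level train/validation/test index sets."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float]
    seed: int


def split_cohort(n: int, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                 seed: int = 0) -> SplitSpec:
    """Random seeded partition of n subjects into train/validation/test."""
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train - 1) if n_train + n_val >= n else n_val
    return SplitSpec(
        train_idx=np.sort(perm[:n_train]),
        val_idx=np.sort(perm[n_train:n_train + n_val]),
        test_idx=np.sort(perm[n_train + n_val:]),
        fractions=fractions,
        seed=seed,
    )


@dataclass
class TrainConfig:
    batch_size: int = 512
    learning_rate: float = 1e-4
    n_epochs: int = 100
    checkpoint_every_epoch: bool = True
    selection_metric: str = "roc_auc"  # or "loss"
    bias_init: str = "prevalence"  # or "zero"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.n_epochs <= 0 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class TrainResult:
    """Per-epoch checkpoints (paths or in-memory state dicts) and the
    training history (epoch, train_loss, val_metric)."""

    checkpoints: list
    history: pd.DataFrame
    model: object  # model carrying the final-epoch weights


def _as_arrays(data, phenotypes) -> tuple[np.ndarray, np.ndarray]:
    X = data.genotypes if isinstance(data, GenotypeDataset) else np.asarray(data)
    Y = phenotypes.outcomes if isinstance(phenotypes, PhenotypeMatrix) else np.asarray(phenotypes)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("genotypes and phenotypes have different subject counts")
    return X, Y


def _mean_val_auc(model, X_val: np.ndarray, Y_val: np.ndarray) -> float:
    """Mean ROC AUC over traits with both classes present; NaN if none has."""
    probs = model.predict_proba(X_val)
    if probs.ndim == 1:
        probs = probs[:, None]
    aucs = []
    for t in range(Y_val.shape[1]):
        y = Y_val[:, t]
        if 0 < y.sum() < len(y):
            aucs.append(roc_auc_score(y, probs[:, t]))
    return float(np.mean(aucs)) if aucs else float("nan")


def train(model, data, phenotypes, split: SplitSpec, config: TrainConfig,
          checkpoint_dir: str | Path | None = None) -> TrainResult:
    """Mini-batch Adam training with one checkpoint per epoch.

    ``checkpoint_dir=None`` keeps per-epoch checkpoints as in-memory state
    dicts (fast path for desk-scale studies); otherwise each epoch is
    persisted to ``epoch_###.npz``.  Data is consumed batch-wise; the full
    matrix is only ever indexed, never copied whole.
    """
    X, Y = _as_arrays(data, phenotypes)
    is_stl = isinstance(model, STLModel)
    if config.bias_init == "prevalence":
        train_prev = Y[split.train_idx].mean(axis=0)
        model.set_output_bias(train_prev if not is_stl else train_prev[:1])
    opt = make_optimizer(model, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    Xv, Yv = X[split.val_idx], Y[split.val_idx]

    checkpoints: list = []
    records = []
    n_train = len(split.train_idx)
    for epoch in range(config.n_epochs):
        order = split.train_idx[rng.permutation(n_train)]
        losses = []
        for b0 in range(0, n_train, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            xb = np.asarray(X[idx], dtype=float)
            yb = Y[idx] if not is_stl else Y[idx, 0]
            out = model.loss_and_grads(xb, yb)
            if not np.isfinite(out.total):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {out.total}")
            opt.step(model.grads())
            losses.append(out.total)
        if config.selection_metric == "loss":
            val_metric = -model.loss(Xv, Yv if not is_stl else Yv[:, 0]).total
        else:
            val_metric = _mean_val_auc(model, Xv, Yv)
        if config.checkpoint_every_epoch:
            if checkpoint_dir is None:
                checkpoints.append(model.state_copy())
            else:
                path = Path(checkpoint_dir) / f"epoch_{epoch + 1:03d}.npz"
                save_checkpoint(model, path)
                checkpoints.append(path)
        records.append({"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
                        "val_metric": val_metric})
    history = pd.DataFrame.from_records(records)
    return TrainResult(checkpoints=checkpoints, history=history, model=model)


def select_best_checkpoint(checkpoints: list, model, X_val: np.ndarray,
                           Y_val: np.ndarray, metric: str = "roc_auc"):
    """Return ``(model_with_best_weights, epoch_index)`` by validation
    performance; ties break toward the earliest epoch."""
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    if Y_val.ndim == 1:
        Y_val = Y_val[:, None]
    best_score, best_i = -np.inf, 0
    for i, ckpt in enumerate(checkpoints):
        _restore(model, ckpt)
        if metric == "loss":
            y = Y_val if not isinstance(model, STLModel) else Y_val[:, 0]
            score = -model.loss(X_val, y).total
        else:
            score = _mean_val_auc(model, X_val, Y_val)
        if np.isfinite(score) and score > best_score:
            best_score, best_i = score, i
    _restore(model, checkpoints[best_i])
    return model, best_i


def _restore(model, ckpt) -> None:
    if isinstance(ckpt, (str, Path)):
        model.load_state(load_checkpoint(ckpt).state())
    else:
        model.load_state(ckpt)


@dataclass
class MetricsRecord:
    """Per-trait test metrics with baselines (0.5 for ROC, prevalence for PR).

    ``table`` columns: trait, prevalence, roc_auc, pr_auc (NaN for traits
    with a single class in the test set, flagged in ``undefined``).
    """

    table: pd.DataFrame
    undefined: list[str] = field(default_factory=list)


def evaluate_metrics(scores: np.ndarray, Y: np.ndarray, trait_names=None) -> MetricsRecord:
    """ROC AUC (rank statistic) and PR AUC (average precision) per trait.

    ``scores`` may be probabilities or any monotone risk score; single-class
    traits are reported as NaN and flagged, never silently 0.
    """
    scores = np.asarray(scores, dtype=float)
    Y = np.asarray(Y)
    if scores.ndim == 1:
        scores = scores[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    d = Y.shape[1]
    if trait_names is None:
        trait_names = [f"trait{t}" for t in range(d)]
    rows, undefined = [], []
    for t in range(d):
        y, s = Y[:, t], scores[:, t]
        prev = float(y.mean())
        if 0 < y.sum() < len(y):
            roc = float(roc_auc_score(y, s))
            pr = float(average_precision_score(y, s))
        else:
            roc = pr = float("nan")
            undefined.append(str(trait_names[t]))
        rows.append({"trait": trait_names[t], "prevalence": prev,
                     "roc_auc": roc, "pr_auc": pr})
    return MetricsRecord(table=pd.DataFrame(rows), undefined=undefined)


def evaluate_model(model, X: np.ndarray, Y: np.ndarray, trait_names=None) -> MetricsRecord:
    return evaluate_metrics(model.predict_proba(np.asarray(X, dtype=float)), Y, trait_names)


def relative_increase(model_auc: float, stl_auc: float, baseline: float) -> float:
    """Over-baseline AUC gain of a model relative to the single-task
    baseline's gain, in percent.  All three values must share units
    (fractions or percent).  Undefined when the STL AUC equals the baseline."""
    denom = stl_auc - baseline
    if denom == 0:
        raise ZeroDivisionError("relative increase undefined: STL AUC equals the baseline")
    return ((model_auc - baseline) - denom) / denom * 100.0
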