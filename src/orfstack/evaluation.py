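"""Confusion-matrix metrics, balanced subsampling and stratified k-fold CV.

The positive class is ``coding`` throughout.  Reported rates are
sensitivity (TPR), precision (PPV), accuracy (ACC) and the F1 score,
the harmonic mean of precision and sensitivity.  Ratios with a zero
denominator are reported as NaN together with an ``undefined`` flag,
never silently as 0.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np

POSITIVE_LABEL = "coding"
NEGATIVE_LABEL = "noncoding"


def f1_score(ppv: float, tpr: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if ppv + tpr == 0:
        return math.nan
    return 2.0 * ppv * tpr / (ppv + tpr)


@dataclasses.dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    ppv: float
    acc: float
    f1: float

    @property
    def undefined(self) -> tuple[str, ...]:
        """Names of rates whose denominator was zero."""
        return tuple(
            name for name in ("tpr", "ppv", "acc", "f1") if math.isnan(getattr(self, name))
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_metrics(predicted: Sequence[str], truth: Sequence[str]) -> Metrics:
    """Confusion counts and TPR/PPV/ACC/F1 with ``coding`` positive."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape[0]} predictions vs {truth.shape[0]} labels"
        )
    pos_p = predicted == POSITIVE_LABEL
    pos_t = truth == POSITIVE_LABEL
    tp = int(np.sum(pos_p & pos_t))
    fp = int(np.sum(pos_p & ~pos_t))
    fn = int(np.sum(~pos_p & pos_t))
    tn = int(np.sum(~pos_p & ~pos_t))
    n = tp + fp + tn + fn
    tpr = tp / (tp + fn) if tp + fn else math.nan
    ppv = tp / (tp + fp) if tp + fp else math.nan
    acc = (tp + tn) / n if n else math.nan
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn, tpr=tpr, ppv=ppv, acc=acc, f1=f1_score(ppv, tpr))


def sample_balanced(
    labels: Sequence[str],
    n_per_class: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Indices of a balanced subsample, ``n_per_class`` per class.

    Sampling is uniform without replacement and deterministic given the
    seed.  Raises if any class has fewer than ``n_per_class`` members.
    """
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_per_class:
            raise ValueError(
                f"class {cls!r} has only {len(idx)} members, need {n_per_class}"
            )
        chosen.append(rng.choice(idx, size=n_per_class, replace=False))
    return np.sort(np.concatenate(chosen))


def stratified_folds(
    labels: Sequence[str],
    k: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Assign each sample a fold id in [0, k) preserving class balance.

    Within each class, shuffled indices are dealt round-robin over the k
    folds, so per-class fold counts differ by at most one.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


@dataclasses.dataclass(frozen=True)
class CvResult:
    fold_metrics: list[Metrics]
    fold_assignment: np.ndarray

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and sample standard deviation (ddof=1) per metric."""
        out = {}
        for name in ("tpr", "ppv", "acc", "f1"):
            vals = np.array([getattr(m, name) for m in self.fold_metrics])
            out[name] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
        return out


def kfold_cv(
    X: np.ndarray,
    labels: Sequence[str],
    train_fn: Callable[[np.ndarray, np.ndarray], object],
    predict_fn: Callable[[object, np.ndarray], np.ndarray],
    k: int = 10,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold cross-validation of an arbitrary classifier.

    ``train_fn(X_train, y_train)`` returns a fitted model and
    ``predict_fn(model, X_test)`` its predicted labels.  Folds are
    disjoint, cover all samples, and each training split must contain
    both classes.
    """
    X = np.asarray(X)
    labels = np.asarray(labels)
    if len(X) != len(labels):
        raise ValueError("X and labels length mismatch")
    fold = stratified_folds(labels, k=k, seed=seed)
    metrics: list[Metrics] = []
    for f in range(k):
        test = fold == f
        train = ~test
        y_train = labels[train]
        if len(set(y_train.tolist())) < 2:
            raise ValueError(f"fold {f}: a class is absent from the training split")
        model = train_fn(X[train], y_train)
        predicted = predict_fn(model, X[test])
        metrics.append(compute_metrics(predicted, labels[test]))
    return CvResult(fold_metrics=metrics, fold_assignment=fold)


def average_rows(
    values: Sequence[Sequence[float]],
    deviations: Sequence[Sequence[float]] | None = None,
) -> tuple[list[float], list[float] | None]:
    """Column means of a results table, in the ``mean +/- sd`` style.

    Used to aggregate per-run metric rows (e.g. repeated-sampling
    experiments): the reported average row is the plain column mean of
    the metric values, and — when per-row deviations are given — the
    column mean of the deviations.
    """
    vals = np.asarray(values, dtype=float)
    mean_vals = np.mean(vals, axis=0).tolist()
    if deviations is None:
        return mean_vals, None
    devs = np.asarray(deviations, dtype=float)
    if devs.shape != vals.shape:
        raise ValueError("values and deviations must have the same shape")
    return mean_vals, np.mean(devs, axis=0).tolist()
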