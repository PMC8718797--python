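"""Cross-validation and classification metrics.

The labelled pair set is split into k folds of near-equal size (stratified
by label by default: indices are shuffled within each class and dealt
round-robin, so fold sizes differ by at most one overall *and* per class).
Each fold is held out once; accuracy, recall, F1 and the Matthews
correlation coefficient are computed from the confusion counts at a 0.5
decision threshold, and the AUC from the full ROC sweep (trapezoidal rule,
equal to the Mann-Whitney pair statistic with ties counted one half).
The mean ROC across folds is assembled by vertical averaging of the fold
curves on a common false-positive-rate grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve, auc as _trapezoid_auc

from .gbdt_lr import GBDTLRClassifier

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "kfold_split",
    "confusion",
    "metrics",
    "roc_auc",
    "cross_validate",
    "CVResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsRecord:
    ACC: float
    Recall: float
    F1: float
    MCC: float
    AUC: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def kfold_split(labels, folds: int = 10, seed: int = 0,
                stratified: bool = True) -> np.ndarray:
    """Fold assignment (0..folds-1) per sample; sizes differ by at most 1.

    Stratified mode shuffles within each class and deals round-robin across
    folds, so the per-class counts per fold also differ by at most 1.
    """
    y = np.asarray(labels)
    n = y.size
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    rng = np.random.default_rng(seed)
    if stratified:
        order = np.concatenate([
            rng.permutation(np.nonzero(y == cls)[0]) for cls in np.unique(y)
        ])
    else:
        order = rng.permutation(n)
    assign = np.empty(n, dtype=np.int64)
    assign[order] = np.arange(n) % folds
    return assign


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts at a decision threshold (predict 1 when score >= t)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (s >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(((pred == 1) & (y == 1)).sum()),
        TN=int(((pred == 0) & (y == 0)).sum()),
        FP=int(((pred == 1) & (y == 0)).sum()),
        FN=int(((pred == 0) & (y == 1)).sum()),
    )


def metrics(counts: ConfusionCounts) -> MetricsRecord:
    """Accuracy, recall, F1 and MCC from confusion counts (AUC left NaN).

    A metric with a zero denominator is reported as NaN with a warning.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN

    def _safe(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                          stacklevel=3)
            return float("nan")
        return num / den

    acc = _safe(tp + tn, counts.total, "accuracy")
    rec = _safe(tp, tp + fn, "recall")
    f1 = _safe(2 * tp, 2 * tp + fp + fn, "F1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe(tp * tn - fp * fn, mcc_den, "MCC")
    return MetricsRecord(ACC=acc, Recall=rec, F1=f1, MCC=mcc)


def roc_auc(scores, labels):
    """AUC (trapezoidal over the full threshold sweep) plus the ROC points."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


@dataclass
class CVResult:
    per_fold: list          # MetricsRecord per fold
    mean: MetricsRecord
    fold_assign: np.ndarray
    mean_roc: tuple         # (fpr grid, mean tpr)
    scores: np.ndarray = field(default=None)  # out-of-fold scores per sample

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i, **m.as_dict()) for i, m in enumerate(self.per_fold)]
        rows.append(dict(fold="mean", **self.mean.as_dict()))
        return pd.DataFrame(rows)


def cross_validate(X, y, estimator: GBDTLRClassifier | None = None,
                   folds: int = 10, seed: int = 0, stratified: bool = True,
                   fpr_grid_size: int = 101) -> CVResult:
    """k-fold CV of the cascade classifier on pair features.

    Trains a fresh clone of ``estimator`` on each train split, scores the
    held-out fold, and reports per-fold and mean metrics plus the vertically
    averaged ROC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if estimator is None:
        estimator = GBDTLRClassifier()
    assign = kfold_split(y, folds=folds, seed=seed, stratified=stratified)
    grid = np.linspace(0.0, 1.0, fpr_grid_size)
    per_fold: list[MetricsRecord] = []
    tprs = []
    oof = np.full(y.size, np.nan)
    for f in range(folds):
        test = assign == f
        clf = estimator.__class__(**estimator.get_params())
        clf.fit(X[~test], y[~test])
        p = clf.predict_proba(X[test])[:, 1]
        oof[test] = p
        rec = metrics(confusion(p, y[test]))
        rec.AUC, fpr, tpr = roc_auc(p, y[test])
        per_fold.append(rec)
        tprs.append(np.interp(grid, fpr, tpr))
    mean = MetricsRecord(
        ACC=float(np.mean([m.ACC for m in per_fold])),
        Recall=float(np.mean([m.Recall for m in per_fold])),
        F1=float(np.mean([m.F1 for m in per_fold])),
        MCC=float(np.mean([m.MCC for m in per_fold])),
        AUC=float(np.mean([m.AUC for m in per_fold])),
    )
    mean_tpr = np.mean(np.vstack(tprs), axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return CVResult(per_fold, mean, assign, (grid, mean_tpr), oof)
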