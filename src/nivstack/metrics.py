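"""Performance measures and benchmark harnesses.

Accuracy, precision, recall, F1 and ROC-AUC (Mann-Whitney rank
formulation, ties counted half), all derived from a single confusion
matrix type.  Zero denominators return 0 with a warning rather than
raising, so degenerate folds don't crash benchmark tables.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "f1_from_confusion",
    "roc_auc",
    "metrics_row",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Counts with positive class = 1 (ventilation failure)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true {y_true.shape} vs y_pred {y_pred.shape}"
        )
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp + cm.tn, cm.total, "accuracy")


def precision(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp, cm.tp + cm.fp, "precision")


def recall(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp, cm.tp + cm.fn, "recall")


def f1(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if p == 0 and r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def f1_from_confusion(cm: ConfusionMatrix) -> float:
    return _safe_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1")


def roc_auc(y_true, scores) -> float:
    """P(random positive outscores random negative), ties counting 1/2.

    Computed from the rank-sum of positive scores (midranks for ties),
    equivalent to integrating the ROC curve.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(scores)
    rank_sum = ranks[y_true == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metrics_row(y_true, scores, threshold: float = 0.5, name: str = "") -> dict:
    """The five-measure row used throughout the benchmark tables."""
    y_pred = (np.asarray(scores, float) >= threshold).astype(int)
    cm = confusion(y_true, y_pred)
    p = precision(cm)
    r = recall(cm)
    return {
        "name": name,
        "accuracy": accuracy(cm),
        "auc": roc_auc(y_true, scores),
        "f1": f1(p, r),
        "precision": p,
        "recall": r,
        "tp": cm.tp,
        "fp": cm.fp,
        "fn": cm.fn,
        "tn": cm.tn,
    }
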