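"""Classifier evaluation: confusion matrix, rates, ROC curve, threshold.

Conventions follow the clinical-prognosis use of this package: the
positive class is long survival (">10 months"), reliability is the
per-predicted-row correct fraction (positive/negative predictive value),
and accuracy is the plain correct-prediction proportion — which, as the
usual caveat goes, is misleading under heavy class imbalance (an
all-negative classifier on a 1:99 split scores 0.99), hence the ROC
machinery alongside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "confusion_matrix",
    "accuracy",
    "rates",
    "roc_curve",
    "select_threshold",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Fourfold table of a binary classifier's decisions."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: object = 1

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_matrix(predicted, actual, positive_label=1) -> ConfusionMatrix:
    """Count TP/FP/FN/TN for binary label sequences of equal length."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be equal-length 1-d sequences")
    labels = set(np.unique(predicted)) | set(np.unique(actual))
    if positive_label not in labels:
        labels.add(positive_label)
    if len(labels) > 2:
        raise ValueError(f"more than two labels present: {sorted(labels)}")
    pos_p = predicted == positive_label
    pos_a = actual == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_p & pos_a)),
        fp=int(np.sum(pos_p & ~pos_a)),
        fn=int(np.sum(~pos_p & pos_a)),
        tn=int(np.sum(~pos_p & ~pos_a)),
        positive_label=positive_label,
    )


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def rates(cm: ConfusionMatrix) -> dict[str, float]:
    """TPR, FPR and per-predicted-row reliability.

    TPR = TP/(TP+FN); FPR = FP/(TN+FP); reliability of the predicted-
    positive row = TP/(TP+FP), of the predicted-negative row = TN/(TN+FN).
    """
    out = {}
    for key, num, den in [
        ("tpr", cm.tp, cm.tp + cm.fn),
        ("fpr", cm.fp, cm.tn + cm.fp),
        ("reliability_positive", cm.tp, cm.tp + cm.fp),
        ("reliability_negative", cm.tn, cm.tn + cm.fn),
    ]:
        if den == 0:
            raise ZeroDivisionError(f"rate {key!r} undefined: zero denominator")
        out[key] = num / den
    return out


@dataclass(frozen=True)
class RocCurve:
    """ROC points, threshold-ordered from (0, 0) to (1, 1), with AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (np.all(np.diff(self.fpr) >= 0) and np.all(np.diff(self.tpr) >= 0)):
            raise ValueError("ROC coordinates must be nondecreasing")


def roc_curve(probabilities, actual, positive_label=1) -> RocCurve:
    """ROC of positive-class probabilities against true labels.

    Thresholds sweep the unique predicted probabilities (plus sentinels
    at each end); the area under the curve is the trapezoid-rule
    integral, which for a step curve equals the concordance probability
    with ties counted one half.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    actual = np.asarray(actual)
    if probabilities.min() < 0 or probabilities.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    y = (actual == positive_label).astype(int)
    if y.min() == y.max():
        raise ValueError("AUC undefined: only one class present in actual labels")
    fpr, tpr, thr = _sk_roc_curve(y, probabilities, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def select_threshold(probabilities, actual, positive_label=1) -> float:
    """Accuracy-maximizing decision threshold.

    Candidates are the unique predicted probabilities plus the boundary
    0.0 (under the strict ``p > t`` rule, 0.0 yields the all-positive
    classifier unless some probability is exactly 0).  Ties are broken
    toward the smaller threshold.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    actual = np.asarray(actual)
    y = (actual == positive_label).astype(int)
    if y.min() == y.max():
        warnings.warn("only one class present; threshold selection is degenerate",
                      stacklevel=2)
    candidates = np.concatenate([[0.0], np.unique(probabilities)])
    best_t, best_acc = 0.0, -1.0
    for t in candidates:
        pred = (probabilities > t).astype(int)
        acc = float(np.mean(pred == y))
        if acc > best_acc:
            best_t, best_acc = float(t), acc
    return best_t
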