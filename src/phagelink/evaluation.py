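"""Binary-classification metrics for interaction prediction.

Accuracy, precision, recall, F1 and the false discovery rate are computed
from an explicit confusion matrix; ROC/AUROC uses the threshold sweep with
trapezoidal integration (delegated to scikit-learn), which equals the
Mann-Whitney concordance probability.  Metrics whose denominator is zero
return the :data:`UNDEFINED` marker rather than raising or silently
yielding 0, so aggregation across datasets can skip them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "UNDEFINED",
    "Undefined",
    "ConfusionMatrix",
    "MetricBundle",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "fdr",
    "roc_curve_and_auc",
    "metric_bundle",
]


class Undefined:
    """Singleton marker for a metric with a zero denominator."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = Undefined()

MetricValue = float | Undefined


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricBundle:
    accuracy: MetricValue
    precision: MetricValue
    recall: MetricValue
    f1: MetricValue
    auroc: MetricValue
    fdr: MetricValue

    def as_dict(self) -> dict[str, float]:
        return {
            name: (float("nan") if isinstance(v, Undefined) else v)
            for name, v in vars(self).items()
        }


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    """Count the four classification outcomes for binary labels."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if y.size == 0:
        raise ValueError("empty input")
    if not (set(np.unique(y)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def accuracy(cm: ConfusionMatrix) -> MetricValue:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return (cm.tp + cm.tn) / cm.total if cm.total else UNDEFINED


def precision(cm: ConfusionMatrix) -> MetricValue:
    """TP / (TP + FP)."""
    return cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else UNDEFINED


def recall(cm: ConfusionMatrix) -> MetricValue:
    """TP / (TP + FN)."""
    return cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else UNDEFINED


def f1(cm: ConfusionMatrix) -> MetricValue:
    """Harmonic mean of precision and recall, 2PR / (P + R)."""
    p, r = precision(cm), recall(cm)
    if isinstance(p, Undefined) or isinstance(r, Undefined) or p + r == 0:
        return UNDEFINED
    return 2 * p * r / (p + r)


def fdr(cm: ConfusionMatrix) -> MetricValue:
    """False discovery rate FP / (TP + FP): 1 - precision."""
    return cm.fp / (cm.tp + cm.fp) if cm.tp + cm.fp else UNDEFINED


def roc_curve_and_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr, threshold) and the trapezoidal AUROC.

    Requires both classes present; equal scores are grouped into a single
    threshold, which makes the AUROC equal the tie-corrected concordance
    probability (0.5 for constant scores).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(set(np.unique(y))) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    points = np.column_stack([fpr, tpr, thresholds])
    return points, float(_sk_auc(fpr, tpr))


def metric_bundle(
    labels: Sequence[int],
    predictions: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricBundle:
    """All metrics at once; AUROC requires ``scores``."""
    cm = confusion(labels, predictions)
    if scores is not None:
        _, auroc = roc_curve_and_auc(labels, scores)
    else:
        auroc = UNDEFINED
    return MetricBundle(
        accuracy=accuracy(cm),
        precision=precision(cm),
        recall=recall(cm),
        f1=f1(cm),
        auroc=auroc,
        fdr=fdr(cm),
    )
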