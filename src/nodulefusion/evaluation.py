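"""Binary-classification metrics: confusion matrix, accuracy, sensitivity,
specificity, F1, ROC curve, and AUC.

The positive class is the preinvasive lesion (PIL). Sensitivity is the
true-positive rate among diseased cases (low values mean missed lesions);
specificity is the true-negative rate (low values mean false alarms). F1 is
the harmonic mean of precision and sensitivity for the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics_from_confusion", "roc_auc"]


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float = float("nan")
    roc_points: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
        }


def confusion(labels, predictions, threshold: float | None = None) -> ConfusionMatrix:
    """Cross-tabulate true labels against (optionally thresholded) predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if threshold is not None:
        p = (p >= threshold).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, and positive-class F1 from counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = _safe_div(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = _safe_div(cm.tn, cm.tn + cm.fp, "specificity")
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, f1=f1)


def roc_auc(labels, scores):
    """ROC by sweeping all score thresholds (ties grouped) and trapezoidal AUC.

    Returns ``(roc_points, auc)`` where ``roc_points`` is a list of
    ``(fpr, tpr)`` pairs running from (0, 0) to (1, 1).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc
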