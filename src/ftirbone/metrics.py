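"""Binary classification metrics used across the duration and fracture models."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ClassMetrics", "ModelEval", "auc", "class_metrics"]


@dataclass(frozen=True)
class ClassMetrics:
    """Precision, sensitivity (recall) and their harmonic mean for one class."""

    precision: float
    sensitivity: float
    f1: float

    def __post_init__(self) -> None:
        for name in ("precision", "sensitivity", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        p, s = self.precision, self.sensitivity
        expected = 2 * p * s / (p + s) if p + s > 0 else 0.0
        if abs(self.f1 - expected) > 1e-9:
            raise ValueError("f1 must equal the harmonic mean of precision and sensitivity")

    @classmethod
    def from_precision_sensitivity(cls, precision: float, sensitivity: float) -> "ClassMetrics":
        f1 = (
            2 * precision * sensitivity / (precision + sensitivity)
            if precision + sensitivity > 0
            else 0.0
        )
        return cls(precision, sensitivity, f1)


@dataclass(frozen=True)
class ModelEval:
    """Mean cross-validated performance of one model configuration.

    ``per_class`` maps the class label (0 = first/negative, 1 =
    second/positive) to its :class:`ClassMetrics`.  Per-class F-1 is the
    harmonic mean of the repeat-averaged precision and sensitivity.
    """

    auc: float
    accuracy: float
    per_class: dict[int, ClassMetrics]
    n_repeats: int
    seed: int

    def __post_init__(self) -> None:
        for name, v in (("auc", self.auc), ("accuracy", self.accuracy)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_row(self) -> dict[str, float]:
        """Flat grid row: AUC, accuracy, then per-class precision/sensitivity/F-1."""
        row: dict[str, float] = {"auc": self.auc, "accuracy": self.accuracy}
        for label, prefix in ((0, "class0"), (1, "class1")):
            cm = self.per_class[label]
            row[f"{prefix}_precision"] = cm.precision
            row[f"{prefix}_sensitivity"] = cm.sensitivity
            row[f"{prefix}_f1"] = cm.f1
        return row


def auc(scores, labels) -> float:
    """Area under the ROC curve; ties count one half.

    Equals the probability that a random positive outranks a random
    negative (trapezoidal ROC area).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def class_metrics(predicted, labels, positive_class) -> ClassMetrics:
    """Precision and sensitivity of ``positive_class``; empty denominators give 0."""
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    if predicted.size == 0:
        raise ValueError("empty predictions")
    tp = np.sum((predicted == positive_class) & (labels == positive_class))
    fp = np.sum((predicted == positive_class) & (labels != positive_class))
    fn = np.sum((predicted != positive_class) & (labels == positive_class))
    if tp + fp == 0:
        warnings.warn(f"no predictions of class {positive_class!r}; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn(f"no instances of class {positive_class!r}; sensitivity set to 0")
        sensitivity = 0.0
    else:
        sensitivity = tp / (tp + fn)
    return ClassMetrics.from_precision_sensitivity(float(precision), float(sensitivity))
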