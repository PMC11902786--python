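"""Confusion-matrix construction and classification agreement metrics.

All three headline metrics consume an integer C x C count matrix (rows =
true class, columns = predicted class), so the arithmetic stays exact up
to the final divisions:

* overall accuracy  OA = sum_i TP_i / sum_i Total_i  (= Po),
* average accuracy  AA = (1/C) sum_i TP_i / Total_i,
* Cohen's kappa     kappa = (Po - Pe) / (1 - Pe)  with the expected
  chance agreement Pe = sum_i row_i * col_i / n^2.

OA weights classes by their sample counts; AA weights them equally, so
the two coincide exactly on balanced class counts. Kappa corrects OA for
agreement expected by chance and never exceeds it while Pe < 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["confusion_matrix", "overall_accuracy", "average_accuracy",
           "kappa", "MetricsReport", "evaluate"]


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with counts[i, j] = #{true == i and pred == j}."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D label arrays")
    if y_true.size < 1:
        raise ValueError("need at least one sample")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _check_cm(cm) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    if cm.sum() == 0:
        raise ValueError("confusion matrix is empty")
    return cm.astype(np.int64)


def overall_accuracy(cm) -> float:
    cm = _check_cm(cm)
    return float(np.trace(cm) / cm.sum())


def average_accuracy(cm) -> float:
    """Unweighted mean of per-class accuracies; undefined (raises) when a
    class has zero true samples — drop empty classes explicitly first."""
    cm = _check_cm(cm)
    totals = cm.sum(axis=1)
    if np.any(totals == 0):
        empty = np.flatnonzero(totals == 0).tolist()
        raise ValueError(f"average accuracy undefined: classes {empty} have no true samples")
    return float(np.mean(np.diag(cm) / totals))


def kappa(cm) -> float:
    """Chance-corrected agreement (Po - Pe) / (1 - Pe)."""
    cm = _check_cm(cm)
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float(cm.sum(axis=1) @ cm.sum(axis=0)) / float(n) ** 2
    if pe >= 1.0:
        raise ValueError("kappa undefined: expected agreement Pe = 1 (degenerate matrix)")
    return float((po - pe) / (1.0 - pe))


@dataclass
class MetricsReport:
    """The evaluation summary attached to every fold/run."""

    OA: float
    AA: float
    Kappa: float
    per_class_accuracy: np.ndarray
    Po: float
    Pe: float
    confusion: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "OA": self.OA, "AA": self.AA, "Kappa": self.Kappa,
            "Po": self.Po, "Pe": self.Pe,
            "per_class_accuracy": [float(a) for a in self.per_class_accuracy],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def summary(self) -> str:
        """Table-style one-liner, percentages at 2 decimals."""
        return (f"OA {100 * self.OA:.2f}%  AA {100 * self.AA:.2f}%  "
                f"Kappa {self.Kappa:.4f}")


def evaluate(y_true, y_pred, n_classes: int) -> MetricsReport:
    """Build the confusion matrix and compute all metrics in one call."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    totals = cm.sum(axis=1)
    present = totals > 0
    per_class = np.full(n_classes, np.nan)
    per_class[present] = np.diag(cm)[present] / totals[present]
    n = cm.sum()
    po = float(np.trace(cm) / n)
    pe = float(cm.sum(axis=1) @ cm.sum(axis=0)) / float(n) ** 2
    aa = average_accuracy(cm) if present.all() else float(np.nanmean(per_class))
    return MetricsReport(OA=overall_accuracy(cm), AA=aa, Kappa=kappa(cm),
                         per_class_accuracy=per_class, Po=po, Pe=pe,
                         confusion=cm)
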