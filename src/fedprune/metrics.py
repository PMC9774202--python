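"""Confusion matrix, accuracy, and macro precision/recall.

The confusion matrix is an n×n integer count table with rows indexed by the
true class and columns by the predicted class; for the binary case its cells
are the familiar TP/FN/FP/TN.  Accuracy is the trace over the total
(equivalently (TP+TN)/(TP+TN+FP+FN) for n=2).  Precision and recall are
computed per class — precision_c = cm[c,c]/column-sum, recall_c =
cm[c,c]/row-sum — and macro-averaged over the classes where the denominator
is nonzero; classes with undefined terms are excluded from the mean and
logged rather than silently zero-filled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

__all__ = ["confusion", "accuracy", "precision", "recall",
           "per_class_precision", "per_class_recall", "MetricReport", "report",
           "confusion_to_csv"]

logger = logging.getLogger(__name__)


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int],
              n_classes: int) -> np.ndarray:
    """Count matrix: ``cm[i, j] = #{samples with true i, predicted j}``."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted label lists differ in length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError("labels out of range [0, n_classes)")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def _check(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any():
        raise ValueError("confusion matrix must be square and non-negative")
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Fraction of correctly classified samples: trace / total."""
    cm = _check(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("accuracy undefined on zero samples")
    return float(np.trace(cm) / total)


def per_class_precision(cm: np.ndarray) -> np.ndarray:
    """Per-class precision; NaN where the class was never predicted."""
    cm = _check(cm)
    col = cm.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(col > 0, np.diag(cm) / col, np.nan)


def per_class_recall(cm: np.ndarray) -> np.ndarray:
    """Per-class recall; NaN where the class has no true samples."""
    cm = _check(cm)
    row = cm.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(row > 0, np.diag(cm) / row, np.nan)


def _macro(values: np.ndarray, what: str) -> float:
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        raise ValueError(f"{what} undefined for every class")
    n_excluded = int(np.isnan(values).sum())
    if n_excluded:
        logger.info("%s: excluded %d class(es) with undefined value from macro mean",
                    what, n_excluded)
    return float(defined.mean())


def precision(cm: np.ndarray) -> float:
    """Macro-averaged precision over classes that were predicted at least once."""
    return _macro(per_class_precision(cm), "precision")


def recall(cm: np.ndarray) -> float:
    """Macro-averaged recall over classes with at least one true sample."""
    return _macro(per_class_recall(cm), "recall")


def confusion_to_csv(cm: np.ndarray, class_labels: Sequence = None) -> str:
    """CSV text: header of predicted labels, one row per true label."""
    cm = _check(cm)
    labels = list(class_labels) if class_labels is not None else list(range(len(cm)))
    if len(labels) != len(cm):
        raise ValueError("class_labels length must match the matrix size")
    lines = ["true\\pred," + ",".join(str(l) for l in labels)]
    for lab, row in zip(labels, cm):
        lines.append(f"{lab}," + ",".join(str(int(v)) for v in row))
    return "\n".join(lines) + "\n"


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    per_class_precision: List[float] = field(default_factory=list)
    per_class_recall: List[float] = field(default_factory=list)

    def to_json(self) -> str:
        def clean(v):
            return None if (isinstance(v, float) and np.isnan(v)) else v

        return json.dumps({
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "per_class_precision": [clean(v) for v in self.per_class_precision],
            "per_class_recall": [clean(v) for v in self.per_class_recall],
        }, indent=2)


def report(true_labels: Sequence[int], predicted_labels: Sequence[int],
           n_classes: int) -> MetricReport:
    cm = confusion(true_labels, predicted_labels, n_classes)
    return MetricReport(
        accuracy=accuracy(cm),
        precision=precision(cm),
        recall=recall(cm),
        per_class_precision=[float(v) for v in per_class_precision(cm)],
        per_class_recall=[float(v) for v in per_class_recall(cm)],
    )
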