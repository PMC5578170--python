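"""Binary-classification metrics used throughout the evaluation.

Accuracy, sensitivity and specificity are exact functions of the
confusion counts:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    SN  = TP / (TP + FN)
    Spec = TN / (TN + FP)

Threshold-free quality is summarized by the area under the ROC curve
(trapezoidal integration) and the area under the precision-recall curve
in its step-wise (average-precision) form — linear PR interpolation is
deliberately avoided because it inflates AUPR on skewed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Counts for +/-1 labels and +/-1 (or thresholded-score) predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(pos & (y_pred == 1))),
        tn=int(np.sum(~pos & (y_pred != 1))),
        fp=int(np.sum(~pos & (y_pred == 1))),
        fn=int(np.sum(pos & (y_pred != 1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fp)


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration."""
    return float(roc_auc_score(y_true, scores))


def aupr(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise area under the precision-recall curve (average precision)."""
    return float(average_precision_score(y_true, scores))


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(FPR, TPR, threshold) rows for plotting/export."""
    fpr, tpr, thr = roc_curve(y_true, scores)
    return np.column_stack([fpr, tpr, thr])


def pr_points(y_true: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(recall, precision) rows for plotting/export."""
    precision, recall, _ = precision_recall_curve(y_true, scores)
    return np.column_stack([recall, precision])
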