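"""Segmentation and counting metrics: per-class IoU, mIoU, mA, RRMSE, R²."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EvalReport", "CountSeries", "evaluate_segmentation", "rrmse", "pearson_r2"]


@dataclass
class EvalReport:
    per_class_iou: np.ndarray
    mean_iou: float
    mean_accuracy: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "per_class_iou": [float(v) for v in self.per_class_iou],
            "mean_iou": self.mean_iou,
            "mean_accuracy": self.mean_accuracy,
            "n_points": self.n_points,
        }


@dataclass
class CountSeries:
    """Paired ground-truth and predicted ear counts across clouds."""

    ground_truth: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.ground_truth = np.asarray(self.ground_truth, dtype=np.float64)
        self.predicted = np.asarray(self.predicted, dtype=np.float64)
        if self.ground_truth.shape != self.predicted.shape:
            raise ValueError("count series must have equal lengths")


def evaluate_segmentation(labels: np.ndarray, predictions: np.ndarray, n_classes: int) -> EvalReport:
    """Per-class intersection-over-union, their mean, and point accuracy.

    ``IoU_k`` compares the index sets of class ``k`` in ground truth and
    prediction; a class absent from both gets IoU 1 by convention so the
    mean stays defined on clouds lacking a class.  Mean accuracy is the
    fraction of correctly labeled points.
    """
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape or labels.ndim != 1:
        raise ValueError("labels and predictions must be equal-length vectors")
    for name, arr in (("labels", labels), ("predictions", predictions)):
        if arr.min() < 1 or arr.max() > n_classes:
            raise ValueError(f"{name} out of range {{1..{n_classes}}}")
    iou = np.empty(n_classes)
    for k in range(1, n_classes + 1):
        truth = labels == k
        pred = predictions == k
        union = np.logical_or(truth, pred).sum()
        iou[k - 1] = 1.0 if union == 0 else np.logical_and(truth, pred).sum() / union
    return EvalReport(
        per_class_iou=iou,
        mean_iou=float(iou.mean()),
        mean_accuracy=float((labels == predictions).mean()),
        n_points=labels.size,
    )


def rrmse(series: CountSeries) -> tuple[float, int]:
    """Root relative mean square error of counts, each error scaled by truth.

    Pairs with a ground-truth count of zero cannot be relatively scaled and
    are excluded; the number of excluded pairs is returned alongside.
    """
    b = series.ground_truth
    bh = series.predicted
    keep = b != 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("RRMSE undefined: all ground-truth counts are zero")
    rel = (b[keep] - bh[keep]) / b[keep]
    return float(np.sqrt(np.mean(rel ** 2))), n_excluded


def pearson_r2(series: CountSeries) -> float:
    """Squared Pearson correlation between true and predicted counts."""
    b = series.ground_truth
    bh = series.predicted
    if b.size < 2:
        raise ValueError("need at least two pairs for a correlation")
    if np.ptp(b) == 0 or np.ptp(bh) == 0:
        raise ValueError("Pearson correlation undefined for a constant series")
    r = stats.pearsonr(b, bh).statistic
    return float(r * r)
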