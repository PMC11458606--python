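"""Segmentation and classification metrics.

Overlap metrics (Dice similarity coefficient, intersection-over-union)
compare a predicted and a reference label mask one class at a time; mean
IoU averages over the classes present in the reference.  Classification
metrics come from explicit confusion counts, and the ROC curve/AUC use a
threshold sweep over the unique scores with trapezoidal integration.
Degenerate denominators return NaN with a warning rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = [
    "ConfusionCounts",
    "dice",
    "iou",
    "mean_iou",
    "recall",
    "precision",
    "accuracy",
    "confusion_from_labels",
    "roc_auc",
    "aggregate_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _binarize(pred: np.ndarray, truth: np.ndarray, class_id: int) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred == class_id, truth == class_id


def dice(pred: np.ndarray, truth: np.ndarray, class_id: int = 1) -> float:
    """2|X∩Y| / (|X| + |Y|); both masks empty scores 1.0 (agreement on absence)."""
    x, y = _binarize(pred, truth, class_id)
    denom = x.sum() + y.sum()
    if denom == 0:
        warnings.warn(f"class {class_id} absent from both masks; Dice = 1.0 by convention")
        return 1.0
    return float(2.0 * np.logical_and(x, y).sum() / denom)


def iou(pred: np.ndarray, truth: np.ndarray, class_id: int = 1) -> float:
    """|X∩Y| / |X∪Y|; both masks empty scores 1.0."""
    x, y = _binarize(pred, truth, class_id)
    union = np.logical_or(x, y).sum()
    if union == 0:
        warnings.warn(f"class {class_id} absent from both masks; IoU = 1.0 by convention")
        return 1.0
    return float(np.logical_and(x, y).sum() / union)


def mean_iou(pred: np.ndarray, truth: np.ndarray, classes=None) -> float:
    """Unweighted mean IoU over the classes present in the reference mask."""
    truth = np.asarray(truth)
    if classes is None:
        classes = np.unique(truth)
    vals = [iou(pred, truth, class_id=int(c)) for c in classes]
    if not vals:
        raise ValueError("no classes to average")
    return float(np.mean(vals))


def recall(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN with a warning when no positives exist."""
    denom = counts.tp + counts.fn
    if denom == 0:
        warnings.warn("recall undefined: no positive reference units")
        return float("nan")
    return counts.tp / denom


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN with a warning when nothing was predicted positive."""
    denom = counts.tp + counts.fp
    if denom == 0:
        warnings.warn("precision undefined: no positive predictions")
        return float("nan")
    return counts.tp / denom


def accuracy(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        warnings.warn("accuracy undefined: no evaluated units")
        return float("nan")
    return (counts.tp + counts.tn) / counts.total


def confusion_from_labels(pred_labels, true_labels, positive) -> ConfusionCounts:
    p = np.asarray(list(pred_labels)) == positive
    t = np.asarray(list(true_labels)) == positive
    if p.shape != t.shape:
        raise ValueError("label sequences differ in length")
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)),
    )


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve ((fpr, tpr) rows) and trapezoidal AUC.

    Thresholds sweep the unique scores from high to low; tied scores share
    a threshold.  Labels may be {0, 1} or {"low", "high"}.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab in (1, True, "high") else 0 for lab in labels])
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one sample of each class")
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    tps = np.cumsum(yy)
    fps = np.cumsum(1 - yy)
    # keep the last index of each tied-score run, prepend the (0, 0) origin
    keep = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _round_half_up(x: float, places: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


def aggregate_metrics(per_structure: dict) -> dict:
    """Unweighted mean of each metric across structures, rounded half-up to 2 dp.

    ``per_structure`` maps structure name -> {metric name -> value}; every
    row must carry the same metric keys.  Stored per-structure values are
    never rounded; rounding applies only to this aggregate report.
    """
    if not per_structure:
        raise ValueError("need at least one structure row")
    rows = list(per_structure.values())
    keys = list(rows[0].keys())
    for name, row in per_structure.items():
        if list(row.keys()) != keys:
            raise ValueError(f"structure {name!r} has inconsistent metric keys")
    return {k: _round_half_up(float(np.mean([r[k] for r in rows]))) for k in keys}
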