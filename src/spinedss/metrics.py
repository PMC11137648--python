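"""Evaluation metrics for the pipeline.

Pixel-overlap and classification metrics are all derived from TP/TN/FP/FN
tallies; segmentation quality uses the Dice similarity coefficient (DSC) and
intersection-over-union (IoU), which satisfy the identity
``DSC = 2*IoU / (1 + IoU)``. Inter-rater agreement for reader studies uses
Fleiss' kappa. Ratio metrics with a zero denominator raise
:class:`~spinedss.exceptions.UndefinedMetricError` instead of silently
returning 0, because silent zeros corrupt averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats import inter_rater

from .exceptions import UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative tallies (items or pixels)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_masks(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion tallies between two binary masks of equal shape."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"mask shapes differ: {pred.shape} vs {truth.shape}"
        )
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN) — recall of the positive class."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """TN / (FP + TN)."""
    return _ratio(c.tn, c.fp + c.tn, "specificity")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (FP + 2TP + FN)."""
    return _ratio(2 * c.tp, c.fp + 2 * c.tp + c.fn, "DSC")


def iou(c: ConfusionCounts) -> float:
    """Intersection over union TP / (FP + TP + FN)."""
    return _ratio(c.tp, c.fp + c.tp + c.fn, "IoU")


def dsc_from_iou(iou_value: float) -> float:
    """Convert IoU to DSC via the identity DSC = 2*IoU / (1 + IoU)."""
    if not 0.0 <= iou_value <= 1.0:
        raise ValidationError("IoU must lie in [0, 1]")
    return 2.0 * iou_value / (1.0 + iou_value)


# ---------------------------------------------------------------------------
# multi-class helpers (one-vs-rest per class, micro accuracy)
# ---------------------------------------------------------------------------

def per_class_counts(
    pred: Sequence, truth: Sequence, classes: Sequence | None = None
) -> dict:
    """One-vs-rest ConfusionCounts per class from two label sequences."""
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValidationError("prediction/truth label lists differ in length")
    if classes is None:
        classes = sorted(set(pred) | set(truth))
    out = {}
    for cls in classes:
        tp = sum(1 for p, t in zip(pred, truth) if p == cls and t == cls)
        fp = sum(1 for p, t in zip(pred, truth) if p == cls and t != cls)
        fn = sum(1 for p, t in zip(pred, truth) if p != cls and t == cls)
        tn = len(pred) - tp - fp - fn
        out[cls] = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return out


def micro_accuracy(pred: Sequence, truth: Sequence) -> float:
    """Fraction of exactly matching labels (trace / total)."""
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValidationError("prediction/truth label lists differ in length")
    if not pred:
        raise UndefinedMetricError("accuracy undefined on empty label lists")
    return sum(p == t for p, t in zip(pred, truth)) / len(pred)


# ---------------------------------------------------------------------------
# Fleiss' kappa
# ---------------------------------------------------------------------------

def fleiss_kappa(table: np.ndarray) -> float:
    """Fleiss' (1971) chance-corrected agreement for a fixed rater panel.

    ``table`` is an N-items x k-categories count matrix whose rows all sum to
    the number of raters n >= 2. Returns exactly 1.0 when every item is rated
    unanimously.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1 or table.shape[1] < 2:
        raise ValidationError("rating table must be N x k with k >= 2")
    if np.any(table < 0):
        raise ValidationError("rating counts must be nonnegative")
    row_sums = table.sum(axis=1)
    n = row_sums[0]
    if n < 2:
        raise ValidationError("Fleiss' kappa needs at least 2 raters")
    if not np.allclose(row_sums, n):
        raise ValidationError("rating table rows must all sum to the rater count")
    return float(inter_rater.fleiss_kappa(table, method="fleiss"))


# ---------------------------------------------------------------------------
# reader-study arithmetic
# ---------------------------------------------------------------------------

def _mean_std(value) -> tuple[float, float | None]:
    if np.isscalar(value):
        return float(value), None
    arr = np.asarray(value, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


@dataclass(frozen=True)
class TaskComparison:
    task: str
    accuracy_unassisted: float
    accuracy_assisted: float
    time_unassisted: float
    time_assisted: float
    accuracy_improvement_pct: float
    time_reduction_pct: float


def reader_study_summary(
    unassisted: Mapping[str, Mapping[str, object]],
    assisted: Mapping[str, Mapping[str, object]],
) -> dict:
    """Relative accuracy improvement and time reduction per task, plus means.

    ``unassisted`` and ``assisted`` map task name -> {"accuracy": ..,
    "time_s": ..} where each entry is either a scalar (already a mean) or a
    per-reader sequence, in which case the mean is taken. Improvements are
    relative: (assisted - unassisted) / unassisted for accuracy and
    (unassisted - assisted) / unassisted for time, reported as percentages
    rounded to 2 decimals.
    """
    if set(unassisted) != set(assisted):
        raise ValidationError("unassisted and assisted task lists differ")
    tasks = []
    for name in unassisted:
        acc_u, _ = _mean_std(unassisted[name]["accuracy"])
        acc_a, _ = _mean_std(assisted[name]["accuracy"])
        t_u, _ = _mean_std(unassisted[name]["time_s"])
        t_a, _ = _mean_std(assisted[name]["time_s"])
        if acc_u <= 0 or t_u <= 0:
            raise UndefinedMetricError(
                f"relative change undefined for task {name!r}: zero baseline"
            )
        tasks.append(
            TaskComparison(
                task=name,
                accuracy_unassisted=acc_u,
                accuracy_assisted=acc_a,
                time_unassisted=t_u,
                time_assisted=t_a,
                accuracy_improvement_pct=round((acc_a - acc_u) / acc_u * 100.0, 2),
                time_reduction_pct=round((t_u - t_a) / t_u * 100.0, 2),
            )
        )
    mean_acc = round(
        float(np.mean([t.accuracy_improvement_pct for t in tasks])), 2
    )
    mean_time = round(float(np.mean([t.time_reduction_pct for t in tasks])), 2)
    return {
        "tasks": tasks,
        "mean_accuracy_improvement_pct": mean_acc,
        "mean_time_reduction_pct": mean_time,
    }
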