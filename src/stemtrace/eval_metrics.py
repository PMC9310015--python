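"""Detection and counting evaluation metrics.

Detections are matched to ground truth greedily in descending confidence
at a fixed IoU threshold (default 0.5); a ground-truth box is consumed by
at most one detection.  From the ranked match flags the module computes
precision, recall, F1, the non-interpolated average precision (cumulative
precision times recall increment over the ranked list), and mAP as the
unweighted mean over classes.  Counting accuracy is summarized by MAE,
MSE, RMSE, the coefficient of determination (1 - SSres/SStot) and
Pearson's r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .geometry import BBox, iou

__all__ = [
    "MatchResult",
    "RegressionMetrics",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "mean_average_precision",
    "regression_metrics",
]


@dataclass(frozen=True)
class MatchResult:
    """Per-class match counts plus the per-detection flags ordered by
    descending confidence (True = matched a ground-truth box)."""

    tp: int
    fp: int
    fn: int
    flags: tuple[bool, ...]


def match_detections(
    dets: Sequence[BBox],
    gts: Sequence[BBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ordered matching of detections to ground truth.

    Each detection claims the unmatched ground-truth box of highest IoU at
    or above the threshold; unmatched detections are false positives and
    unmatched ground-truth boxes false negatives.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    taken = [False] * len(gts)
    flags = [False] * len(dets)
    for i in order:
        best_j = -1
        best_iou = iou_threshold
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = iou(dets[i], g)
            if v >= iou_threshold and (best_j < 0 or v > best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            flags[i] = True
    ranked = tuple(flags[i] for i in order)
    tp = sum(ranked)
    return MatchResult(tp=tp, fp=len(dets) - tp, fn=len(gts) - tp, flags=ranked)


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, F1); 0/0 ratios resolve to 0."""
    precision = m.tp / (m.tp + m.fp) if m.tp + m.fp else 0.0
    recall = m.tp / (m.tp + m.fn) if m.tp + m.fn else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def average_precision(flags: Sequence[bool], n_gt: int) -> float:
    """Non-interpolated AP over a confidence-ranked match-flag list.

    ``sum_k precision(k) * delta_recall(k)`` with ``delta_recall`` equal to
    ``1 / n_gt`` at each true positive and 0 elsewhere.  Defined as 0 when
    there is no ground truth or no detection.
    """
    if n_gt < 0:
        raise InputError("n_gt must be non-negative")
    if n_gt == 0 or not flags:
        return 0.0
    tp = 0
    ap = 0.0
    for k, flag in enumerate(flags, start=1):
        if flag:
            tp += 1
            ap += (tp / k) / n_gt
    return ap


def mean_average_precision(per_class_ap: Mapping[str, float]) -> float:
    """Unweighted mean AP over classes."""
    if not per_class_ap:
        raise InputError("mAP needs at least one class")
    return sum(per_class_ap.values()) / len(per_class_ap)


@dataclass(frozen=True)
class RegressionMetrics:
    """Error and agreement summary between true and inferred counts.

    ``r_squared`` and ``pearson_r`` are NaN when the denominator variance
    vanishes (constant truth or constant prediction)."""

    mae: float
    mse: float
    rmse: float
    r_squared: float
    pearson_r: float


def regression_metrics(
    truth: Sequence[float], pred: Sequence[float]
) -> RegressionMetrics:
    """MAE, MSE, RMSE, coefficient of determination and Pearson's r."""
    t = np.asarray(truth, dtype=np.float64)
    c = np.asarray(pred, dtype=np.float64)
    if t.shape != c.shape or t.ndim != 1:
        raise InputError("truth and pred must be 1-D sequences of equal length")
    if t.size < 2:
        raise InputError("at least two pairs are required")
    resid = t - c
    mae = float(np.abs(resid).mean())
    mse = float((resid**2).mean())
    rmse = math.sqrt(mse)
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r_squared = math.nan
    else:
        r_squared = 1.0 - float((resid**2).sum()) / ss_tot
    if ss_tot == 0.0 or float(((c - c.mean()) ** 2).sum()) == 0.0:
        pearson = math.nan
    else:
        pearson = float(np.corrcoef(t, c)[0, 1])
    return RegressionMetrics(
        mae=mae, mse=mse, rmse=rmse, r_squared=r_squared, pearson_r=pearson
    )
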