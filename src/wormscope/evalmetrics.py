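"""Detection evaluation: IoU, greedy matching, P/R/F1 and Pascal-VOC AP.

Predictions are matched to ground-truth instances greedily in descending
confidence order; a prediction matches the unmatched ground truth of
highest IoU provided that IoU reaches the minimum (0.5 by convention).
Unmatched ground truths are false negatives, unmatched predictions false
positives. Average precision is the area under the interpolated
precision-recall curve, sampled at every recall value where the precision
envelope changes (the all-points interpolation of VOC 2010+). Matching can
use either pixel-mask IoU or bounding-box IoU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detproc import Detection, _score_order
from .instances import InstanceMask

__all__ = [
    "MatchResult",
    "Metrics",
    "PRCurve",
    "mask_iou",
    "box_iou",
    "match_detections",
    "precision_recall_f1",
    "f1_score",
    "average_precision",
    "iou_sweep",
]


def mask_iou(a: InstanceMask, b: InstanceMask) -> float:
    """Pixel-set intersection over union of two instance masks."""
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    return inter / union


def box_iou(a, b) -> float:
    """IoU of two half-open boxes ``(x0, y0, x1, y1)``."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    if ax0 >= ax1 or ay0 >= ay1 or bx0 >= bx1 or by0 >= by1:
        raise ValueError("degenerate box")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


@dataclass
class MatchResult:
    """TP/FP/FN bookkeeping of one prediction-to-ground-truth matching."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]]  # (prediction id, gt index, IoU)
    iou_min: float

    @property
    def avg_iou(self) -> float:
        """Mean IoU over matched pairs (NaN when nothing matched)."""
        if not self.pairs:
            return float("nan")
        return float(np.mean([iou for _, _, iou in self.pairs]))


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    avg_mask_iou: float = float("nan")


@dataclass
class PRCurve:
    """Score-ranked precision-recall curve and its interpolated area."""

    recalls: np.ndarray
    precisions: np.ndarray
    ap: float
    iou_min: float


def _pred_iou(pred: Detection, gt: InstanceMask, mode: str) -> float:
    if mode == "mask":
        if pred.mask is None:
            raise ValueError("prediction lacks a mask; use mode='box'")
        return mask_iou(pred.mask, gt)
    return box_iou(pred.bbox, gt.bbox)


def match_detections(
    preds: list[Detection],
    gts: list[InstanceMask],
    iou_min: float = 0.5,
    mode: str = "mask",
) -> MatchResult:
    """Greedy confidence-ordered matching with single-use ground truths."""
    if mode not in ("mask", "box"):
        raise ValueError("mode must be 'mask' or 'box'")
    flags = _match_flags(preds, gts, iou_min, mode)
    pairs = [(p.id, g, iou) for p, (g, iou) in zip(_score_order(preds), flags) if g >= 0]
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp, pairs=pairs, iou_min=iou_min)


def _match_flags(preds, gts, iou_min, mode) -> list[tuple[int, float]]:
    """Per prediction (score order): (matched gt index or -1, its IoU)."""
    taken = [False] * len(gts)
    out = []
    for p in _score_order(preds):
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            iou = _pred_iou(p, g, mode)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_min:
            taken[best_j] = True
            out.append((best_j, best_iou))
        else:
            out.append((-1, 0.0))
    return out


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(m: MatchResult) -> Metrics:
    """P = tp/(tp+fp), R = tp/(tp+fn), F1 their harmonic mean.

    Degenerate denominators yield NaN with a warning rather than an error,
    so empty plates and empty detection sets survive batch evaluation.
    """
    if m.tp + m.fp > 0:
        precision = m.tp / (m.tp + m.fp)
    else:
        warnings.warn("precision undefined: no predictions", stacklevel=2)
        precision = float("nan")
    if m.tp + m.fn > 0:
        recall = m.tp / (m.tp + m.fn)
    else:
        warnings.warn("recall undefined: no ground truths", stacklevel=2)
        recall = float("nan")
    if np.isnan(precision) or np.isnan(recall):
        f1 = float("nan")
    else:
        f1 = f1_score(precision, recall)
    return Metrics(precision=precision, recall=recall, f1=f1, avg_mask_iou=m.avg_iou)


def average_precision(
    preds: list[Detection],
    gts: list[InstanceMask],
    iou_min: float = 0.5,
    mode: str = "mask",
) -> PRCurve:
    """All-points interpolated AP of the score-ranked detection list.

    The precision envelope p(r) = max precision at recall >= r is integrated
    over the recall increments contributed by each true positive.
    """
    if len(gts) == 0:
        raise ValueError("average precision undefined without ground truths")
    flags = _match_flags(preds, gts, iou_min, mode)
    tp_flags = np.array([g >= 0 for g, _ in flags], dtype=float)
    if tp_flags.size == 0:
        return PRCurve(np.array([]), np.array([]), 0.0, iou_min)
    cum_tp = np.cumsum(tp_flags)
    ranks = np.arange(1, tp_flags.size + 1)
    recalls = cum_tp / len(gts)
    precisions = cum_tp / ranks
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recalls, envelope):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return PRCurve(recalls=recalls, precisions=precisions, ap=float(ap), iou_min=iou_min)


def iou_sweep(
    preds: list[Detection],
    gts: list[InstanceMask],
    thresholds,
    mode: str = "mask",
) -> pd.DataFrame:
    """Evaluate P/R/F1/AP at each minimum-IoU threshold; one row per value."""
    rows = []
    for t in thresholds:
        if not (0.0 < t < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        m = match_detections(preds, gts, iou_min=t, mode=mode)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = precision_recall_f1(m)
        curve = average_precision(preds, gts, iou_min=t, mode=mode)
        rows.append(
            {
                "threshold": t,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "f1": metrics.f1,
                "ap": curve.ap,
                "avg_mask_iou": metrics.avg_mask_iou,
            }
        )
    return pd.DataFrame(rows)
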