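"""Detection evaluation: greedy matching, precision/recall/F1, and
COCO-style interpolated average precision (mAP50, mAP50-95).

Matching follows the usual single-class detection protocol: predictions
are visited in descending confidence (ties by input index) and each one
claims the still-unmatched ground-truth box of highest rotated IoU,
provided that IoU reaches the threshold; otherwise it is a false
positive.  AP uses the COCO 101-point interpolation — the monotone
precision envelope sampled at recalls 0.00, 0.01, ..., 1.00 — and
mAP50-95 averages AP over the ten IoU thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .geometry import OrientedBox, obb_iou

__all__ = [
    "MatchResult",
    "EvalReport",
    "match",
    "precision_recall_f1",
    "average_precision",
    "map50_95",
    "evaluate_detections",
    "evaluate_batch",
    "IOU_THRESHOLDS_50_95",
]

IOU_THRESHOLDS_50_95: Tuple[float, ...] = tuple(
    round(0.50 + 0.05 * k, 2) for k in range(10))


@dataclass
class MatchResult:
    """TP/FP labels for predictions in confidence order.

    ``order`` gives the prediction indices in the visiting order;
    ``tp_flags[k]`` refers to prediction ``order[k]``; ``matched_gt[k]``
    is the claimed ground-truth index or -1.
    """

    tp_flags: np.ndarray
    n_gt: int
    matched_gt: np.ndarray
    order: np.ndarray


def _conf_order(preds: Sequence[OrientedBox]) -> np.ndarray:
    return np.array(sorted(range(len(preds)),
                           key=lambda i: (-preds[i].score, i)), dtype=int)


def match(
    preds: Sequence[OrientedBox],
    gts: Sequence[OrientedBox],
    iou_thresh: float,
) -> MatchResult:
    """Greedily match predictions to ground truth at one IoU threshold.

    Each ground-truth box is matched at most once (every extra
    prediction of the same object is a false positive).
    """
    order = _conf_order(preds)
    tp = np.zeros(len(preds), dtype=bool)
    claimed = np.full(len(preds), -1, dtype=int)
    gt_taken = np.zeros(len(gts), dtype=bool)
    for k, pi in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if gt_taken[j]:
                continue
            iou = obb_iou(preds[pi], gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_thresh:
            tp[k] = True
            claimed[k] = best_j
            gt_taken[best_j] = True
    return MatchResult(tp_flags=tp, n_gt=len(gts), matched_gt=claimed, order=order)


def precision_recall_f1(
    m: MatchResult,
    preds: Sequence[OrientedBox],
    conf_thresh: float = 0.25,
) -> Tuple[float, float, float]:
    """Precision, recall and F1 over predictions scoring >= conf_thresh.

    Confidence selection keeps a prefix of the greedy visiting order, so
    the full-sweep TP labels remain valid for the subset.
    """
    keep = np.array([preds[pi].score >= conf_thresh for pi in m.order],
                    dtype=bool)
    tp = int(m.tp_flags[keep].sum())
    n_pred = int(keep.sum())
    fp = n_pred - tp
    if n_pred == 0:
        precision = 1.0 if m.n_gt == 0 else 0.0
    else:
        precision = tp / n_pred
    if m.n_gt == 0:
        recall = 0.0 if fp > 0 else 1.0
    else:
        recall = tp / m.n_gt
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def _ap_from_flags(tp_flags: np.ndarray, n_gt: int) -> Optional[float]:
    """COCO 101-point AP from TP flags in confidence order."""
    if n_gt == 0:
        return None
    tp_cum = np.cumsum(tp_flags.astype(float))
    fp_cum = np.cumsum((~tp_flags).astype(float))
    n_pred = len(tp_flags)
    if n_pred == 0:
        return 0.0
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone non-increasing precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    sample = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, sample, side="left")
    interp = np.where(idx < n_pred, env[np.minimum(idx, n_pred - 1)], 0.0)
    return float(interp.mean())


def average_precision(
    preds: Sequence[OrientedBox],
    gts: Sequence[OrientedBox],
    iou_thresh: float,
) -> Optional[float]:
    """AP at one IoU threshold over the full confidence sweep.

    None (undefined) when there is no ground truth.
    """
    m = match(preds, gts, iou_thresh)
    return _ap_from_flags(m.tp_flags, m.n_gt)


def map50_95(
    preds: Sequence[OrientedBox],
    gts: Sequence[OrientedBox],
) -> Tuple[Optional[float], Optional[float], Dict[float, Optional[float]]]:
    """(mAP50, mAP50-95, AP per threshold) over 0.50:0.05:0.95."""
    ap_by_iou = {t: average_precision(preds, gts, t) for t in IOU_THRESHOLDS_50_95}
    vals = list(ap_by_iou.values())
    if any(v is None for v in vals):
        return None, None, ap_by_iou
    return ap_by_iou[0.5], float(np.mean(vals)), ap_by_iou


@dataclass
class EvalReport:
    """Aggregate detection metrics at a stated confidence threshold."""

    precision: float
    recall: float
    f1: float
    ap_by_iou: Dict[float, Optional[float]]
    map50: Optional[float]
    map50_95: Optional[float]
    conf_thresh: float
    n_gt: int
    n_pred: int
    max_f1: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "max_f1": self.max_f1,
            "map50": self.map50,
            "map50_95": self.map50_95,
            "ap_by_iou": {f"{k:.2f}": v for k, v in self.ap_by_iou.items()},
            "conf_thresh": self.conf_thresh,
            "n_gt": self.n_gt,
            "n_pred": self.n_pred,
        }


def _max_f1(tp_flags: np.ndarray, n_gt: int) -> Optional[float]:
    """Best F1 over the confidence sweep (threshold-free summary)."""
    if n_gt == 0 or len(tp_flags) == 0:
        return None
    tp_cum = np.cumsum(tp_flags.astype(float))
    k = np.arange(1, len(tp_flags) + 1)
    precision = tp_cum / k
    recall = tp_cum / n_gt
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return float(f1.max())


def evaluate_detections(
    preds: Sequence[OrientedBox],
    gts: Sequence[OrientedBox],
    conf_thresh: float = 0.25,
) -> EvalReport:
    """Full single-image evaluation: P/R/F1 at conf_thresh plus mAPs."""
    m50 = match(preds, gts, 0.5)
    p, r, f1 = precision_recall_f1(m50, preds, conf_thresh)
    map50, m5095, ap_by_iou = map50_95(preds, gts)
    return EvalReport(precision=p, recall=r, f1=f1, ap_by_iou=ap_by_iou,
                      map50=map50, map50_95=m5095, conf_thresh=conf_thresh,
                      n_gt=len(gts), n_pred=len(preds),
                      max_f1=_max_f1(m50.tp_flags, m50.n_gt))


def evaluate_batch(
    pairs: Sequence[Tuple[Sequence[OrientedBox], Sequence[OrientedBox]]],
    conf_thresh: float = 0.25,
    mode: str = "pooled",
) -> EvalReport:
    """Evaluate (predictions, ground-truth) pairs over many images.

    ``pooled`` (COCO-style) matches within each image and pools the
    TP/FP labels across images for one global sweep — with a single
    image it reduces exactly to :func:`evaluate_detections`.
    ``per_image`` averages per-image AP (images without ground truth
    are skipped for AP).
    """
    if mode not in ("pooled", "per_image"):
        raise ValidationError(f"unknown batch mode {mode!r}")
    if mode == "per_image":
        reports = [evaluate_detections(p, g, conf_thresh) for p, g in pairs]
        def _mean(vals):
            vals = [v for v in vals if v is not None]
            return float(np.mean(vals)) if vals else None
        ap_by_iou = {t: _mean([r.ap_by_iou[t] for r in reports])
                     for t in IOU_THRESHOLDS_50_95}
        return EvalReport(
            precision=float(np.mean([r.precision for r in reports])),
            recall=float(np.mean([r.recall for r in reports])),
            f1=float(np.mean([r.f1 for r in reports])),
            ap_by_iou=ap_by_iou,
            map50=ap_by_iou[0.5],
            map50_95=_mean(list(ap_by_iou.values())),
            conf_thresh=conf_thresh,
            n_gt=sum(len(g) for _, g in pairs),
            n_pred=sum(len(p) for p, _ in pairs),
            max_f1=_mean([r.max_f1 for r in reports]),
        )

    # pooled: per-image matching, global confidence sweep
    ap_by_iou: Dict[float, Optional[float]] = {}
    n_gt_total = sum(len(g) for _, g in pairs)
    pooled50 = None
    for t in IOU_THRESHOLDS_50_95:
        scores: List[float] = []
        flags: List[bool] = []
        for preds, gts in pairs:
            m = match(preds, gts, t)
            for k, pi in enumerate(m.order):
                scores.append(preds[pi].score)
                flags.append(bool(m.tp_flags[k]))
        order = np.array(sorted(range(len(scores)),
                                key=lambda i: (-scores[i], i)), dtype=int)
        tp_flags = np.array(flags, dtype=bool)[order]
        ap_by_iou[t] = _ap_from_flags(tp_flags, n_gt_total)
        if t == 0.5:
            pooled50 = (tp_flags, np.array(scores)[order])
    vals = list(ap_by_iou.values())
    m5095 = None if any(v is None for v in vals) else float(np.mean(vals))

    # P/R/F1 at conf_thresh from the pooled IoU-0.5 labels
    tp_flags50, scores50 = pooled50
    keep = scores50 >= conf_thresh
    tp = int(tp_flags50[keep].sum())
    n_pred_kept = int(keep.sum())
    fp = n_pred_kept - tp
    if n_pred_kept == 0:
        precision = 1.0 if n_gt_total == 0 else 0.0
    else:
        precision = tp / n_pred_kept
    if n_gt_total == 0:
        recall = 0.0 if fp > 0 else 1.0
    else:
        recall = tp / n_gt_total
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EvalReport(precision=precision, recall=recall, f1=f1,
                      ap_by_iou=ap_by_iou, map50=ap_by_iou[0.5],
                      map50_95=m5095, conf_thresh=conf_thresh,
                      n_gt=n_gt_total, n_pred=sum(len(p) for p, _ in pairs),
                      max_f1=_max_f1(tp_flags50, n_gt_total))
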