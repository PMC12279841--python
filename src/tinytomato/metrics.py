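"""Detection evaluation: greedy matching, precision/recall, AP, mAP, counting.

Matching follows the standard greedy VOC protocol: detections are visited
in descending confidence; each claims the highest-IoU unmatched ground
truth of the *same class* with IoU at or above the threshold (a true
positive), otherwise it is a false positive; unmatched ground truths are
false negatives.  AP is the area under the precision-envelope-vs-recall
curve with all-point interpolation, P = TP/(TP+FP), R = TP/(TP+FN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .boxes import iou
from .data import CLASS_NAMES, Annotation, Detection, boxes_array

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "PRCurve",
    "match_detections",
    "precision_recall",
    "average_precision",
    "pr_curve",
    "mean_ap",
    "evaluate_dataset",
    "count_by_class",
]


@dataclass
class MatchResult:
    """Per-detection TP/FP flags (confidence-descending order) and FN count."""

    tp: np.ndarray            # bool, aligned with `order`
    confidences: np.ndarray   # descending
    order: np.ndarray         # indices into the original detection list
    n_gt: int
    iou_threshold: float

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    ap: float
    class_id: int | None = None


def match_detections(dets: list[Detection], gts: list[Annotation],
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy class-strict matching of one image's detections to ground truth."""
    order = np.argsort([-d.confidence for d in dets], kind="stable")
    tp = np.zeros(len(dets), dtype=bool)
    confs = np.array([dets[i].confidence for i in order], dtype=float)
    gt_boxes = boxes_array(gts)
    gt_cls = np.array([g.class_id for g in gts], dtype=int)
    claimed = np.zeros(len(gts), dtype=bool)
    for rank, idx in enumerate(order):
        d = dets[idx]
        cand = np.flatnonzero((gt_cls == d.class_id) & ~claimed)
        if cand.size == 0:
            continue
        ious = iou(np.tile(d.box.to_array(), (cand.size, 1)), gt_boxes[cand])
        best = int(np.argmax(ious))
        if ious[best] >= iou_threshold:
            claimed[cand[best]] = True
            tp[rank] = True
    return MatchResult(tp=tp, confidences=confs, order=order,
                       n_gt=len(gts), iou_threshold=iou_threshold)


def precision_recall(n_tp: int, n_fp: int, n_fn: int) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); empty denominators give 0 by convention."""
    if n_tp + n_fp == 0:
        logger.debug("precision undefined (no detections); returning 0 by convention")
        p = 0.0
    else:
        p = n_tp / (n_tp + n_fp)
    if n_tp + n_fn == 0:
        logger.debug("recall undefined (no ground truths); returning 0 by convention")
        r = 0.0
    else:
        r = n_tp / (n_tp + n_fn)
    return p, r


def pr_curve(confidences: np.ndarray, tp: np.ndarray, n_gt: int,
             class_id: int | None = None) -> PRCurve:
    """Cumulative PR points over descending confidence, with all-point AP."""
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = np.asarray(tp, dtype=bool)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt if n_gt > 0 else np.zeros_like(cum_tp, dtype=float)
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    # precision envelope: for each recall level, the best precision at >= that recall
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_ext = np.concatenate([[0.0], recall])
    ap = float(np.sum((r_ext[1:] - r_ext[:-1]) * env))
    return PRCurve(recall=recall, precision=precision, ap=ap, class_id=class_id)


def average_precision(images: list[tuple[list[Detection], list[Annotation]]],
                      class_id: int, iou_threshold: float = 0.5) -> float | None:
    """Dataset-pooled AP for one class; None when the class has no ground truth."""
    confs, flags, n_gt = [], [], 0
    for dets, gts in images:
        dets_c = [d for d in dets if d.class_id == class_id]
        gts_c = [g for g in gts if g.class_id == class_id]
        n_gt += len(gts_c)
        m = match_detections(dets_c, gts_c, iou_threshold)
        confs.append(m.confidences)
        flags.append(m.tp)
    if n_gt == 0:
        logger.info("class %d has no ground truth; AP undefined and excluded", class_id)
        return None
    confs = np.concatenate(confs) if confs else np.array([])
    flags = np.concatenate(flags) if flags else np.array([], dtype=bool)
    if confs.size == 0:
        return 0.0
    return pr_curve(confs, flags, n_gt, class_id).ap


def mean_ap(aps) -> float:
    """Arithmetic mean over classes with defined AP."""
    vals = [a for a in aps if a is not None]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def evaluate_dataset(images: list[tuple[list[Detection], list[Annotation]]],
                     num_classes: int = len(CLASS_NAMES),
                     iou_threshold: float = 0.5,
                     coco_thresholds: bool = False) -> dict:
    """Full evaluation: per-class AP/P/R, mAP50, and the threshold-averaged mAP.

    The threshold-averaged variant ("mAP50-90") averages matching thresholds
    0.50:0.05:0.90 (9 values); ``coco_thresholds=True`` selects the COCO
    0.50:0.05:0.95 convention instead.
    """
    per_class_ap = {c: average_precision(images, c, iou_threshold) for c in range(num_classes)}
    stats = {}
    for c in range(num_classes):
        tp = fp = fn = 0
        for dets, gts in images:
            m = match_detections([d for d in dets if d.class_id == c],
                                 [g for g in gts if g.class_id == c], iou_threshold)
            tp, fp, fn = tp + m.n_tp, fp + m.n_fp, fn + m.n_fn
        p, r = precision_recall(tp, fp, fn)
        stats[c] = {"ap": per_class_ap[c], "precision": p, "recall": r,
                    "tp": tp, "fp": fp, "fn": fn}
    hi = 0.95 if coco_thresholds else 0.90
    thresholds = np.arange(0.5, hi + 1e-9, 0.05)
    ap_per_thr = [
        mean_ap([average_precision(images, c, t) for c in range(num_classes)])
        for t in thresholds
    ]
    return {
        "per_class": stats,
        "map50": mean_ap(per_class_ap.values()),
        "map50_90": float(np.nanmean(ap_per_thr)),
        "iou_threshold": iou_threshold,
    }


def subset_average_precision(images: list[tuple[list[Detection], list[Annotation]]],
                             class_id: int, predicate,
                             iou_threshold: float = 0.5) -> float | None:
    """AP restricted to ground truths selected by `predicate` (e.g. tiny boxes).

    Detections that match an out-of-subset ground truth are ignored — they
    are neither TP nor FP — so the score reflects performance on the subset
    alone (the small-object evaluation convention).
    """
    confs, flags, n_gt = [], [], 0
    for dets, gts in images:
        dets_c = [d for d in dets if d.class_id == class_id]
        inside = [g for g in gts if g.class_id == class_id and predicate(g)]
        outside = [g for g in gts if g.class_id == class_id and not predicate(g)]
        n_gt += len(inside)
        m_in = match_detections(dets_c, inside, iou_threshold)
        m_out = match_detections(dets_c, outside, iou_threshold)
        out_rank = {idx: r for r, idx in enumerate(m_out.order)}
        for r, idx in enumerate(m_in.order):
            if m_in.tp[r]:
                confs.append(m_in.confidences[r])
                flags.append(True)
            elif not m_out.tp[out_rank[idx]]:
                confs.append(m_in.confidences[r])
                flags.append(False)
    if n_gt == 0:
        return None
    if not confs:
        return 0.0
    return pr_curve(np.array(confs), np.array(flags), n_gt, class_id).ap


def tiny_subset_map50(images, num_classes: int = len(CLASS_NAMES),
                      tag: str = "tiny") -> float:
    """mAP50 over the tiny-instance subset (occlusion tag based)."""
    return mean_ap([
        subset_average_precision(images, c, lambda g: g.occlusion == tag)
        for c in range(num_classes)
    ])


def count_by_class(dets: list[Detection], class_names=CLASS_NAMES) -> dict:
    """Per-ripeness-class fruit counts from post-NMS detections."""
    counts = {name: 0 for name in class_names}
    for d in dets:
        counts[class_names[d.class_id]] += 1
    counts["total"] = len(dets)
    return counts
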