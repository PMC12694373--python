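"""COCO-style detection evaluation: IoU, average precision, mAP.

Boxes are axis-aligned ``(x_min, y_min, x_max, y_max)`` in pixels, half-open.
Matching is greedy in descending confidence: each detection claims the
still-unmatched ground truth of its class and image with the highest IoU, and
counts as a true positive when that IoU reaches the threshold.  AP integrates
the precision-recall curve either with COCO's 101-point interpolation
(default) or with the all-point (continuous envelope) rule; mAP averages AP
over classes, and mAP@0.50:0.95 additionally over IoU thresholds 0.50 to 0.95
in steps of 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Detection", "GroundTruth", "EvalResult", "iou", "box_iou_matrix",
    "average_precision", "map_eval", "COCO_THRESHOLDS", "nms",
]

COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    """One predicted box with its class and confidence."""

    image_id: int
    category_id: int
    box: tuple
    score: float

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not np.isfinite(self.score):
            raise ValueError("confidence must be finite")
        if x1 < x0 or y1 < y0:
            raise ValueError(f"invalid box {self.box}")


@dataclass(frozen=True)
class GroundTruth:
    image_id: int
    category_id: int
    box: tuple


def iou(a, b) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint or degenerate."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    if union <= 0:
        return 0.0
    return float(inter / union)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) box arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    iw = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0)
    ih = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0)
    inter = iw * ih
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])).clip(min=0)
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])).clip(min=0)
    union = area_a[:, None] + area_b[None, :] - inter
    out = np.zeros_like(inter)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def _match_class(dets, gts, iou_threshold):
    """Greedy confidence-ordered matching for one class.

    Returns (tp flags, fp flags, scores, n_gt) with detections sorted by
    descending confidence.  Each ground truth is consumed at most once.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    gts_by_image: dict = {}
    for j, g in enumerate(gts):
        gts_by_image.setdefault(g.image_id, []).append(j)
    matched = set()
    tp = np.zeros(len(dets), dtype=bool)
    scores = np.array([dets[i].score for i in order], dtype=np.float64)
    for rank, i in enumerate(order):
        d = dets[i]
        best_iou, best_j = 0.0, -1
        for j in gts_by_image.get(d.image_id, ()):
            if j in matched:
                continue
            v = iou(d.box, gts[j].box)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[rank] = True
            matched.add(best_j)
    return tp, ~tp, scores, len(gts)


def _ap_from_pr(tp, fp, n_gt, interpolation):
    if n_gt == 0:
        raise ValueError("no ground truths for this class")
    if len(tp) == 0:
        return 0.0, np.array([]), np.array([])
    ctp = np.cumsum(tp)
    cfp = np.cumsum(fp)
    recall = ctp / n_gt
    precision = ctp / (ctp + cfp)
    if interpolation == "allpoint":
        r = np.concatenate([[0.0], recall, [1.0]])
        p = np.concatenate([[0.0], precision, [0.0]])
        # precision envelope, then integrate where recall changes
        for k in range(len(p) - 2, -1, -1):
            p[k] = max(p[k], p[k + 1])
        idx = np.where(r[1:] != r[:-1])[0]
        ap = float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
    elif interpolation == "101point":
        rec_points = np.linspace(0.0, 1.0, 101)
        # max precision at recall >= r, via right-to-left running max; the
        # tiny slack keeps float noise in the grid from skipping exact ties
        p_env = np.maximum.accumulate(precision[::-1])[::-1]
        idx = np.searchsorted(recall, rec_points - 1e-10, side="left")
        q = np.where(idx < len(p_env), p_env[np.minimum(idx, len(p_env) - 1)], 0.0)
        ap = float(np.mean(q))
    else:
        raise ValueError(f"unknown interpolation rule {interpolation!r}")
    return ap, precision, recall


def average_precision(dets, gts, iou_threshold: float = 0.5,
                      interpolation: str = "101point") -> float:
    """AP for a single class at one IoU threshold."""
    tp, fp, _, n_gt = _match_class(dets, gts, iou_threshold)
    ap, _, _ = _ap_from_pr(tp, fp, n_gt, interpolation)
    return ap


@dataclass
class EvalResult:
    """Per-class APs and the two headline mAP indicators."""

    per_class_ap: dict              # {threshold: {class: ap}}
    map50: float
    map50_95: float
    precision: dict = field(default_factory=dict)   # {class: array} at 0.50
    recall: dict = field(default_factory=dict)


def map_eval(dets, gts, thresholds=None, interpolation: str = "101point") -> EvalResult:
    """Evaluate detections against ground truths over classes and thresholds.

    Classes present in the ground truth define the class set; a class with no
    ground truths anywhere is skipped with a warning.  Detections for unknown
    classes count as nothing (they can never match).
    """
    if thresholds is None:
        thresholds = COCO_THRESHOLDS
    classes = sorted({g.category_id for g in gts})
    if not classes:
        raise ValueError("empty ground-truth category set")
    det_classes = {d.category_id for d in dets}
    for c in det_classes - set(classes):
        warnings.warn(f"class {c} has detections but no ground truths; skipped")

    per_class_ap: dict = {}
    precision, recall = {}, {}
    for thr in thresholds:
        per_class_ap[thr] = {}
        for c in classes:
            dc = [d for d in dets if d.category_id == c]
            gc = [g for g in gts if g.category_id == c]
            tp, fp, _, n_gt = _match_class(dc, gc, thr)
            ap, p, r = _ap_from_pr(tp, fp, n_gt, interpolation)
            per_class_ap[thr][c] = ap
            if abs(thr - 0.5) < 1e-9:
                precision[c], recall[c] = p, r
    means = {thr: float(np.mean(list(v.values()))) for thr, v in per_class_ap.items()}
    map50 = means.get(0.5, float("nan"))
    map50_95 = float(np.mean(list(means.values())))
    return EvalResult(per_class_ap=per_class_ap, map50=map50,
                      map50_95=map50_95, precision=precision, recall=recall)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.5,
        top_k: int = 100) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices by score order."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    order = np.argsort(-np.asarray(scores))
    keep = []
    while order.size and len(keep) < top_k:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = box_iou_matrix(boxes[i][None], boxes[rest])[0]
        order = rest[ious < iou_threshold]
    return np.array(keep, dtype=int)
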