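"""Anchor clustering, best-possible recall and detection evaluation.

Anchors are clustered with K-means on (w, h) pairs (k-means++ seeding,
Euclidean distance by default; a 1-IoU distance is available since both
variants are standard for anchor design).  BPR — best possible recall — is
the fraction of ground-truth shapes that at least one anchor could match
under the per-dimension ratio rule, an upper bound on the recall any
assignment built on those anchors can reach.

Evaluation follows the usual single-stage protocol: greedy one-to-one
matching by descending confidence at each IoU threshold, per-class AP as
the area under the interpolated precision-recall curve (101-point COCO
convention by default, all-point available), mAP as the class mean, and a
confusion matrix with an extra background row/column capturing false and
missed detections.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .losses import iou as box_iou


@dataclass
class AnchorSet:
    """(w, h) priors in input-resolution pixels, grouped per stride level."""

    anchors: Tuple[Tuple[float, float], ...]
    strides: Tuple[int, ...] = ()

    def __post_init__(self):
        self.anchors = tuple((float(w), float(h)) for w, h in self.anchors)
        if any(w <= 0 or h <= 0 for w, h in self.anchors):
            raise ValueError("anchor dimensions must be positive")

    def as_array(self):
        return np.asarray(self.anchors, dtype=float)

    def __len__(self):
        return len(self.anchors)


# Priors re-clustered for the camera-trap subset (input resolution 640):
# 9 anchors over strides {8, 16, 32} for the 3-head layout, 4 anchors over
# {16, 32} for the pruned 2-head layout.
THREE_HEAD_ANCHORS = AnchorSet(
    ((32, 60), (82, 70), (70, 159),
     (140, 139), (144, 294), (245, 202),
     (278, 381), (448, 237), (514, 429)),
    strides=(8, 8, 8, 16, 16, 16, 32, 32, 32))
TWO_HEAD_ANCHORS = AnchorSet(
    ((55, 51), (84, 89), (140, 71), (216, 158)),
    strides=(16, 16, 32, 32))


def _wh_iou(wh, centers):
    """IoU of aligned (w, h) shapes against centers: (n, k)."""
    inter = np.minimum(wh[:, None, 0], centers[None, :, 0]) * \
        np.minimum(wh[:, None, 1], centers[None, :, 1])
    union = wh[:, 0] * wh[:, 1]
    union = union[:, None] + centers[None, :, 0] * centers[None, :, 1] - inter
    return inter / (union + 1e-12)


def kmeans_anchors(box_wh, k, seed=0, metric="euclidean", max_iter=300):
    """Cluster box shapes into ``k`` anchors.

    Deterministic given ``seed``; with ``k`` equal to the number of distinct
    shapes the centers are exactly those shapes.  ``metric`` is
    ``"euclidean"`` (default) or ``"iou"`` (distance 1 - IoU of aligned
    shapes).
    """
    wh = np.asarray(box_wh, dtype=float).reshape(-1, 2)
    if wh.size == 0:
        raise ValueError("empty box list")
    distinct = np.unique(wh, axis=0)
    if k > len(distinct):
        raise ValueError(f"k={k} exceeds the {len(distinct)} distinct shapes")
    rng = np.random.default_rng(seed)

    def dist(points, centers):
        if metric == "iou":
            return 1.0 - _wh_iou(points, centers)
        diff = points[:, None, :] - centers[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))

    # k-means++ seeding
    centers = [wh[rng.integers(len(wh))]]
    while len(centers) < k:
        d2 = dist(wh, np.asarray(centers)).min(axis=1) ** 2
        total = d2.sum()
        if total <= 0:
            # remaining mass is on existing centers; seed from unused distinct shapes
            used = {tuple(c) for c in centers}
            pool = [p for p in distinct if tuple(p) not in used]
            centers.append(pool[rng.integers(len(pool))])
            continue
        centers.append(wh[rng.choice(len(wh), p=d2 / total)])
    centers = np.asarray(centers, dtype=float)

    for _ in range(max_iter):
        assign = dist(wh, centers).argmin(axis=1)
        new = centers.copy()
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                new[j] = members.mean(axis=0)
            else:  # re-seed empty cluster at the farthest point
                far = dist(wh, centers).min(axis=1).argmax()
                new[j] = wh[far]
        if np.allclose(new, centers):
            break
        centers = new
    order = np.lexsort((centers[:, 1], centers[:, 0] * centers[:, 1]))
    return AnchorSet(tuple(map(tuple, centers[order])))


def bpr(anchors: AnchorSet, gt_wh, ratio_threshold=4.0):
    """Best possible recall under the per-dimension ratio rule.

    A ground-truth (w, h) is matchable by anchor (aw, ah) iff
    ``max(w/aw, aw/w, h/ah, ah/h) < ratio_threshold`` (exclusive bound).
    """
    gt = np.asarray(gt_wh, dtype=float).reshape(-1, 2)
    if len(gt) == 0 or len(anchors) == 0:
        raise ValueError("bpr needs non-empty anchors and ground truths")
    a = anchors.as_array()
    rw = gt[:, None, 0] / a[None, :, 0]
    rh = gt[:, None, 1] / a[None, :, 1]
    worst = np.maximum.reduce([rw, 1.0 / rw, rh, 1.0 / rh])
    return float((worst.min(axis=1) < ratio_threshold).mean())


# ---------------------------------------------------------------------------
# mAP
# ---------------------------------------------------------------------------

@dataclass
class Detection:
    image_id: int
    cls: int
    box: np.ndarray        # cxcywh
    confidence: float


@dataclass
class GroundTruth:
    image_id: int
    cls: int
    box: np.ndarray


def _as_det(d):
    if isinstance(d, Detection):
        return d
    return Detection(int(d[0]), int(d[1]), np.asarray(d[2], float), float(d[3]))


def _as_gt(g):
    if isinstance(g, GroundTruth):
        return g
    return GroundTruth(int(g[0]), int(g[1]), np.asarray(g[2], float))


def _match_class(dets: List[Detection], gts: List[GroundTruth], thr):
    """Greedy matching by descending confidence (ties by detection index).

    Returns a boolean TP flag per detection (already confidence-sorted).
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    used: Dict[int, set] = {}
    tp = np.zeros(len(dets), dtype=bool)
    gt_by_img: Dict[int, List[int]] = {}
    for j, g in enumerate(gts):
        gt_by_img.setdefault(g.image_id, []).append(j)
    for rank, i in enumerate(order):
        d = dets[i]
        best, best_iou = -1, thr
        for j in gt_by_img.get(d.image_id, []):
            if j in used.setdefault(d.image_id, set()):
                continue
            v = float(box_iou(d.box, gts[j].box))
            if v >= best_iou:
                best, best_iou = j, v
        if best >= 0:
            used[d.image_id].add(best)
            tp[rank] = True
    confs = np.array([dets[i].confidence for i in order])
    return tp, confs


def _ap_from_pr(tp, n_gt, interpolation="101"):
    if n_gt == 0:
        return 0.0
    if len(tp) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # envelope: precision at recall >= r
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "101":
        pts = np.linspace(0, 1, 101)
        idx = np.searchsorted(recall, pts, side="left")
        vals = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
        return float(vals.mean())
    # all-point: integrate the staircase
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[prec_env[0] if len(prec_env) else 0.0], prec_env])
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def pr_curve(detections, ground_truths, cls, iou_thr):
    """Confidence-ordered (precision, recall) samples for one class."""
    dets = [d for d in map(_as_det, detections) if d.cls == cls]
    gts = [g for g in map(_as_gt, ground_truths) if g.cls == cls]
    tp, confs = _match_class(dets, gts, iou_thr)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / max(len(gts), 1)
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    return precision, recall, confs


def compute_map(detections, ground_truths, iou_thresholds=None,
                num_classes=None, interpolation="101"):
    """mAP over IoU thresholds.

    Returns ``(map50, map5095, per_class_ap)`` where ``per_class_ap`` is the
    AP at threshold 0.5 per class.  Default thresholds are 0.5:0.95 in 0.05
    steps; passing a single threshold evaluates only that one.
    """
    if iou_thresholds is None:
        iou_thresholds = np.arange(0.5, 0.96, 0.05)
    iou_thresholds = np.atleast_1d(np.asarray(iou_thresholds, float))
    dets = [_as_det(d) for d in detections]
    gts = [_as_gt(g) for g in ground_truths]
    if num_classes is None:
        num_classes = int(max([g.cls for g in gts] + [d.cls for d in dets], default=-1)) + 1
    ap = np.zeros((len(iou_thresholds), num_classes))
    for c in range(num_classes):
        dc = [d for d in dets if d.cls == c]
        gc = [g for g in gts if g.cls == c]
        for t, thr in enumerate(iou_thresholds):
            tp, _ = _match_class(dc, gc, thr)
            ap[t, c] = _ap_from_pr(tp, len(gc), interpolation)
    present = [c for c in range(num_classes) if any(g.cls == c for g in gts)]
    if not present:
        return 0.0, 0.0, ap[0]
    map_per_thr = ap[:, present].mean(axis=1)
    i50 = int(np.argmin(np.abs(iou_thresholds - 0.5)))
    return float(map_per_thr[i50]), float(map_per_thr.mean()), ap[i50]


def confusion_matrix(detections, ground_truths, num_classes,
                     iou_thr=0.45, conf_thr=0.25, normalize=True):
    """(classes+1) x (classes+1) matrix; last row/column is background.

    Rows index the true class; a ground truth with no matching detection
    accrues to the background *column* of its row (missed detection), a
    detection with no matching ground truth accrues to the background *row*
    under its predicted class (false detection).
    """
    if not (0 < iou_thr < 1 and 0 < conf_thr < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    dets = [d for d in map(_as_det, detections) if d.confidence >= conf_thr]
    gts = [_as_gt(g) for g in ground_truths]
    m = np.zeros((num_classes + 1, num_classes + 1))
    images = sorted({g.image_id for g in gts} | {d.image_id for d in dets})
    for img in images:
        dl = sorted([d for d in dets if d.image_id == img],
                    key=lambda d: -d.confidence)
        gl = [g for g in gts if g.image_id == img]
        taken = set()
        matched_det = set()
        for di, d in enumerate(dl):
            best, best_iou = -1, iou_thr
            for gi, g in enumerate(gl):
                if gi in taken:
                    continue
                v = float(box_iou(d.box, g.box))
                if v >= best_iou:
                    best, best_iou = gi, v
            if best >= 0:
                taken.add(best)
                matched_det.add(di)
                m[gl[best].cls, d.cls] += 1
        for gi, g in enumerate(gl):
            if gi not in taken:
                m[g.cls, num_classes] += 1      # missed -> background column
        for di, d in enumerate(dl):
            if di not in matched_det:
                m[num_classes, d.cls] += 1      # false -> background row
    if normalize:
        sums = m.sum(axis=1, keepdims=True)
        m = np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)
    return m


def nms(boxes, scores, iou_thr=0.65):
    """Greedy IoU non-maximum suppression; returns kept indices."""
    boxes = np.asarray(boxes, float)
    order = np.argsort(-np.asarray(scores))
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        ious = np.array([float(box_iou(boxes[i], boxes[j])) for j in rest])
        order = rest[ious < iou_thr]
    return keep
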