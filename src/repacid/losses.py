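"""Bounding-box regression and classification losses.

Boxes are ``(cx, cy, w, h)`` arrays (center coordinates plus positive
extents), broadcastable over leading dimensions.  The complete-IoU loss is

    L_CIoU = 1 - IoU + rho^2 / c^2 + beta * v

with ``rho^2`` the squared center distance, ``c^2`` the squared diagonal of
the smallest enclosing box, ``v = (4/pi^2) (atan(w_gt/h_gt) - atan(w/h))^2``
the aspect-ratio penalty and ``beta = v / (1 - IoU + v)`` its automatically
balanced trade-off weight (no hand-set hyper-parameter).  The alpha variant
raises each term to a power alpha >= 1, which trades gradient smoothness for
robustness on small noisy datasets:

    L_alpha-CIoU = 1 - IoU^alpha + (rho^2/c^2)^alpha + beta * v^alpha.

DFL (distribution focal loss) scores a discrete distribution over box-offset
bins against a continuous target; VFL (varifocal loss) is the
quality-weighted asymmetric BCE used for classification.  SIoU is retained
only as the baseline comparator.
"""
from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _corners(box):
    cx, cy, w, h = box[..., 0], box[..., 1], box[..., 2], box[..., 3]
    return cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2


def _validate(box, name="box"):
    box = np.asarray(box, dtype=float)
    if box.shape[-1] != 4:
        raise ValueError(f"{name} must have 4 components (cx, cy, w, h)")
    if np.any(box[..., 2] <= 0) or np.any(box[..., 3] <= 0):
        raise ValueError(f"{name} has degenerate (non-positive) extents")
    return box


def iou(a, b):
    """Intersection over union of two (broadcastable) cxcywh boxes."""
    a, b = _validate(a, "a"), _validate(b, "b")
    ax1, ay1, ax2, ay2 = _corners(a)
    bx1, by1, bx2, by2 = _corners(b)
    iw = np.clip(np.minimum(ax2, bx2) - np.maximum(ax1, bx1), 0, None)
    ih = np.clip(np.minimum(ay2, by2) - np.maximum(ay1, by1), 0, None)
    inter = iw * ih
    union = a[..., 2] * a[..., 3] + b[..., 2] * b[..., 3] - inter
    return inter / (union + _EPS)


def ciou_terms(pred, gt):
    """All CIoU ingredients: IoU, rho^2, c^2, v, beta (audit-friendly)."""
    pred, gt = _validate(pred, "pred"), _validate(gt, "gt")
    i = iou(pred, gt)
    rho2 = (pred[..., 0] - gt[..., 0]) ** 2 + (pred[..., 1] - gt[..., 1]) ** 2
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    cw = np.maximum(px2, gx2) - np.minimum(px1, gx1)
    ch = np.maximum(py2, gy2) - np.minimum(py1, gy1)
    c2 = cw ** 2 + ch ** 2
    d = np.arctan2(gt[..., 2], gt[..., 3]) - np.arctan2(pred[..., 2], pred[..., 3])
    v = (4.0 / np.pi ** 2) * d ** 2
    beta = v / (1.0 - i + v + _EPS)
    return i, rho2, c2, v, beta


def ciou_loss(pred, gt, return_terms=False):
    i, rho2, c2, v, beta = ciou_terms(pred, gt)
    loss = 1.0 - i + rho2 / (c2 + _EPS) + beta * v
    if return_terms:
        return loss, {"iou": i, "rho2": rho2, "c2": c2, "v": v, "beta": beta}
    return loss


def alpha_ciou_loss(pred, gt, alpha=3.0):
    """Power-CIoU; ``alpha = 1`` reduces exactly to :func:`ciou_loss`."""
    if alpha <= 0:
        raise ValueError("alpha must be positive (>= 1 recommended)")
    i, rho2, c2, v, beta = ciou_terms(pred, gt)
    return 1.0 - i ** alpha + (rho2 / (c2 + _EPS)) ** alpha + beta * v ** alpha


def ciou_grad(pred, gt):
    """Analytic gradient of :func:`ciou_loss` w.r.t. the predicted box.

    Standard CIoU practice: the trade-off weight beta is treated as a
    constant of the step (its dependence on w, h, IoU is not
    differentiated).  Returns an array shaped like ``pred``.
    """
    pred, gt = _validate(pred, "pred"), _validate(gt, "gt")
    cx, cy, w, h = (pred[..., k] for k in range(4))
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)

    iw = np.minimum(px2, gx2) - np.maximum(px1, gx1)
    ih = np.minimum(py2, gy2) - np.maximum(py1, gy1)
    overlap = (iw > 0) & (ih > 0)
    iw_c, ih_c = np.clip(iw, 0, None), np.clip(ih, 0, None)
    inter = iw_c * ih_c
    union = w * h + gt[..., 2] * gt[..., 3] - inter
    i = inter / (union + _EPS)

    # d inter / d corners (only where the pred corner is the active bound)
    d_iw_d_px1 = np.where(overlap & (px1 > gx1), -1.0, 0.0)
    d_iw_d_px2 = np.where(overlap & (px2 < gx2), 1.0, 0.0)
    d_ih_d_py1 = np.where(overlap & (py1 > gy1), -1.0, 0.0)
    d_ih_d_py2 = np.where(overlap & (py2 < gy2), 1.0, 0.0)
    dI_dpx1 = ih_c * d_iw_d_px1
    dI_dpx2 = ih_c * d_iw_d_px2
    dI_dpy1 = iw_c * d_ih_d_py1
    dI_dpy2 = iw_c * d_ih_d_py2

    # corner -> (cx, cy, w, h) chain
    dI_dcx = dI_dpx1 + dI_dpx2
    dI_dcy = dI_dpy1 + dI_dpy2
    dI_dw = 0.5 * (dI_dpx2 - dI_dpx1)
    dI_dh = 0.5 * (dI_dpy2 - dI_dpy1)

    dU_dw = h - dI_dw
    dU_dh = w - dI_dh
    denom = (union + _EPS) ** 2
    diou_dcx = dI_dcx * union / denom - inter * (-dI_dcx) / denom
    diou_dcy = dI_dcy * union / denom - inter * (-dI_dcy) / denom
    diou_dw = (dI_dw * union - inter * dU_dw) / denom
    diou_dh = (dI_dh * union - inter * dU_dh) / denom

    # center-distance term
    rho2 = (cx - gt[..., 0]) ** 2 + (cy - gt[..., 1]) ** 2
    cw = np.maximum(px2, gx2) - np.minimum(px1, gx1)
    ch = np.maximum(py2, gy2) - np.minimum(py1, gy1)
    c2 = cw ** 2 + ch ** 2
    # d cw / d pred corners
    dcw_dpx1 = np.where(px1 < gx1, -1.0, 0.0)
    dcw_dpx2 = np.where(px2 > gx2, 1.0, 0.0)
    dch_dpy1 = np.where(py1 < gy1, -1.0, 0.0)
    dch_dpy2 = np.where(py2 > gy2, 1.0, 0.0)
    dc2_dcx = 2 * cw * (dcw_dpx1 + dcw_dpx2)
    dc2_dcy = 2 * ch * (dch_dpy1 + dch_dpy2)
    dc2_dw = 2 * cw * 0.5 * (dcw_dpx2 - dcw_dpx1)
    dc2_dh = 2 * ch * 0.5 * (dch_dpy2 - dch_dpy1)
    drho2_dcx = 2 * (cx - gt[..., 0])
    drho2_dcy = 2 * (cy - gt[..., 1])
    c2e = c2 + _EPS
    dterm_dcx = (drho2_dcx * c2e - rho2 * dc2_dcx) / c2e ** 2
    dterm_dcy = (drho2_dcy * c2e - rho2 * dc2_dcy) / c2e ** 2
    dterm_dw = -rho2 * dc2_dw / c2e ** 2
    dterm_dh = -rho2 * dc2_dh / c2e ** 2

    # aspect-ratio term (beta constant per step)
    d_at = np.arctan2(gt[..., 2], gt[..., 3]) - np.arctan2(w, h)
    v = (4.0 / np.pi ** 2) * d_at ** 2
    beta = v / (1.0 - i + v + _EPS)
    wh2 = w ** 2 + h ** 2
    dv_dw = (8.0 / np.pi ** 2) * d_at * (-h / (wh2 + _EPS))
    dv_dh = (8.0 / np.pi ** 2) * d_at * (w / (wh2 + _EPS))

    g = np.empty_like(pred)
    g[..., 0] = -diou_dcx + dterm_dcx
    g[..., 1] = -diou_dcy + dterm_dcy
    g[..., 2] = -diou_dw + dterm_dw + beta * dv_dw
    g[..., 3] = -diou_dh + dterm_dh + beta * dv_dh
    return g


def dfl_loss(pred_distribution, target_offset):
    """Distribution focal loss over offset bins.

    ``pred_distribution`` holds probabilities over ``n`` bins (last axis,
    summing to 1); the loss is the cross-entropy on the two bins bracketing
    the continuous target, linearly weighted by proximity.
    """
    p = np.asarray(pred_distribution, dtype=float)
    t = np.asarray(target_offset, dtype=float)
    n = p.shape[-1]
    if np.any(t < 0) or np.any(t > n - 1):
        raise ValueError("target offset outside bin range [0, n-1]")
    lo = np.floor(t).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w_hi = t - lo
    w_lo = 1.0 - w_hi
    p_lo = np.take_along_axis(p, lo[..., None], axis=-1)[..., 0]
    p_hi = np.take_along_axis(p, hi[..., None], axis=-1)[..., 0]
    return -(w_lo * np.log(p_lo + _EPS) + w_hi * np.log(p_hi + _EPS))


def vfl_loss(pred_score, target_quality, gamma=2.0, alpha_neg=0.75):
    """Varifocal loss: quality-weighted asymmetric binary cross-entropy.

    Positives (quality q > 0) are weighted by q; negatives are down-weighted
    by ``alpha_neg * p**gamma`` so that easy background dominates less.
    """
    p = np.asarray(pred_score, dtype=float)
    q = np.asarray(target_quality, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("pred_score must lie strictly inside (0, 1)")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("target_quality must lie in [0, 1]")
    bce = -(q * np.log(p) + (1.0 - q) * np.log(1.0 - p))
    weight = np.where(q > 0, q, alpha_neg * p ** gamma)
    return weight * bce


def siou_loss(pred, gt, theta=4.0):
    """Minimal SIoU reference (the replaced baseline loss); angle, distance
    and shape penalties on top of IoU.  Included for ablation parity only.
    """
    pred, gt = _validate(pred, "pred"), _validate(gt, "gt")
    i = iou(pred, gt)
    dx = gt[..., 0] - pred[..., 0]
    dy = gt[..., 1] - pred[..., 1]
    sigma = np.sqrt(dx ** 2 + dy ** 2) + _EPS
    sin_alpha = np.clip(np.abs(dy) / sigma, -1, 1)
    sin_beta = np.clip(np.abs(dx) / sigma, -1, 1)
    sin_a = np.where(sin_alpha > np.sin(np.pi / 4), sin_beta, sin_alpha)
    angle = np.cos(2 * np.arcsin(sin_a) - np.pi / 2)
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    cw = np.maximum(px2, gx2) - np.minimum(px1, gx1) + _EPS
    ch = np.maximum(py2, gy2) - np.minimum(py1, gy1) + _EPS
    gamma = 2.0 - angle
    dist = 2.0 - np.exp(-gamma * (dx / cw) ** 2) - np.exp(-gamma * (dy / ch) ** 2)
    ww = np.abs(pred[..., 2] - gt[..., 2]) / np.maximum(pred[..., 2], gt[..., 2])
    wh = np.abs(pred[..., 3] - gt[..., 3]) / np.maximum(pred[..., 3], gt[..., 3])
    shape = (1 - np.exp(-ww)) ** theta + (1 - np.exp(-wh)) ** theta
    return 1.0 - i + 0.5 * (dist + shape)


BOX_LOSSES = {"ciou": ciou_loss, "alpha_ciou": alpha_ciou_loss, "siou": siou_loss}


def detection_loss(cls_score, cls_quality, pred_boxes, gt_boxes,
                   box_loss="ciou", alpha=3.0, lambda_box=2.5,
                   dfl_pred=None, dfl_target=None, lambda_dfl=0.5):
    """Total loss: VFL + lambda_box * box loss (+ lambda_dfl * DFL).

    The box/DFL terms average over the positive samples supplied; the VFL
    term averages over all scores.  Weights follow the common single-stage
    defaults and are freely configurable.
    """
    if box_loss not in BOX_LOSSES:
        raise KeyError(f"box_loss must be one of {sorted(BOX_LOSSES)}")
    total = float(np.mean(vfl_loss(cls_score, cls_quality)))
    if len(np.atleast_2d(pred_boxes)):
        if box_loss == "alpha_ciou":
            box = alpha_ciou_loss(pred_boxes, gt_boxes, alpha=alpha)
        else:
            box = BOX_LOSSES[box_loss](pred_boxes, gt_boxes)
        total += lambda_box * float(np.mean(box))
    if dfl_pred is not None:
        total += lambda_dfl * float(np.mean(dfl_loss(dfl_pred, dfl_target)))
    return total
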