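"""Dataset plumbing and the synthetic camera-trap scene generator.

Annotation dialects
-------------------
COCO-style boxes are ``[x, y, w, h]`` with ``(x, y)`` the top-left corner in
pixels of a ``W x H`` image; the normalized per-image label format stores
``class cx cy w h`` with the centroid and extents scaled by ``1/W, 1/H`` so
a resize never invalidates labels.

Synthetic scenes
----------------
Real camera-trap frames are high-resolution, often dark, noisy or blurred,
and contain at most a few animals against woodland clutter.  The generator
emulates that structure: textured backgrounds, one parametric animal
silhouette per class (ellipse composites with class-specific aspect,
legs, tail and coat pattern), day/night illumination and optional
blur/noise/overexposure degradations.  Scene geometry is a pure function of
the scene seed and is stored normalized, so the same scene can be rendered
at full camera resolution or at training size with consistent labels.
Seven classes mirror the camera-trap species subset; the default class
image counts (191, 302, 253, 214, 346, 229, 239 — 1774 in total, each
within the 100-500 range typical of rare-species subsets) and the 8:1:1
per-class split reproduce the reference dataset arithmetic exactly.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

CLASS_NAMES = (
    "spotted_linsang",
    "blue_whistling_thrush",
    "red_muntjac",
    "chevrotain",
    "large_indian_civet",
    "macaque",
    "red_shanked_douc",
)
NUM_CLASSES = len(CLASS_NAMES)
DEFAULT_CLASS_COUNTS = (191, 302, 253, 214, 346, 229, 239)   # sums to 1774
RESOLUTIONS = ((2560, 1920), (3264, 2448), (4000, 3000), (4992, 2808))
AUGMENTATIONS = ("flip", "hsv", "noise")


# ---------------------------------------------------------------------------
# Annotation dialects
# ---------------------------------------------------------------------------

@dataclass
class CocoAnnotation:
    image_id: int
    width: int
    height: int
    category: int
    bbox: Tuple[float, float, float, float]      # x, y, w, h (top-left, pixels)


@dataclass
class YoloLabel:
    cls: int
    cx: float
    cy: float
    w: float
    h: float

    def as_array(self):
        return np.array([self.cx, self.cy, self.w, self.h])


def coco_to_yolo(ann: CocoAnnotation, clamp=True) -> YoloLabel:
    """Convert a top-left pixel box to a normalized centroid box.

    ``cx = (x + w/2)/W`` etc.  Out-of-bounds boxes are clamped into the
    image with a warning when ``clamp`` is set, otherwise rejected.
    """
    x, y, w, h = ann.bbox
    W, H = float(ann.width), float(ann.height)
    if w <= 0 or h <= 0:
        raise ValueError("degenerate bbox")
    if x < 0 or y < 0 or x + w > W or y + h > H:
        if not clamp:
            raise ValueError(f"bbox {ann.bbox} outside image {W}x{H}")
        warnings.warn(f"clamping out-of-bounds bbox {ann.bbox} on image {ann.image_id}")
        x0, y0 = max(x, 0.0), max(y, 0.0)
        x1, y1 = min(x + w, W), min(y + h, H)
        x, y, w, h = x0, y0, x1 - x0, y1 - y0
    return YoloLabel(ann.category, (x + w / 2) / W, (y + h / 2) / H, w / W, h / H)


def yolo_to_coco(label: YoloLabel, width: int, height: int, image_id=0) -> CocoAnnotation:
    w, h = label.w * width, label.h * height
    x = label.cx * width - w / 2
    y = label.cy * height - h / 2
    return CocoAnnotation(image_id, width, height, label.cls, (x, y, w, h))


def write_yolo_labels(path, labels: Sequence[YoloLabel]):
    with open(path, "w") as fh:
        for l in labels:
            fh.write(f"{l.cls} {l.cx:.6f} {l.cy:.6f} {l.w:.6f} {l.h:.6f}\n")


def read_yolo_labels(path) -> List[YoloLabel]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                out.append(YoloLabel(int(parts[0]), *map(float, parts[1:5])))
    return out


def write_coco_json(path, annotations: Sequence[CocoAnnotation],
                    class_names=CLASS_NAMES):
    images, seen = [], set()
    for a in annotations:
        if a.image_id not in seen:
            seen.add(a.image_id)
            images.append({"id": a.image_id, "width": a.width, "height": a.height})
    payload = {
        "images": images,
        "annotations": [
            {"id": i, "image_id": a.image_id, "category_id": a.category,
             "bbox": list(map(float, a.bbox)),
             "area": float(a.bbox[2] * a.bbox[3]), "iscrowd": 0}
            for i, a in enumerate(annotations)],
        "categories": [{"id": i, "name": n} for i, n in enumerate(class_names)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_coco_json(path) -> List[CocoAnnotation]:
    with open(path) as fh:
        payload = json.load(fh)
    dims = {im["id"]: (im["width"], im["height"]) for im in payload["images"]}
    return [CocoAnnotation(a["image_id"], *dims[a["image_id"]],
                           a["category_id"], tuple(a["bbox"]))
            for a in payload["annotations"]]


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    width: int = 2560
    height: int = 1920
    class_id: int = 0
    n_objects: int = 1
    illumination: str = "day"                 # day | night
    degradation: str = "none"                 # none | blur | noise | overexposure
    scale_range: Tuple[float, float] = (0.12, 0.45)   # object size / min image dim
    seed: int = 0


# per-class silhouette parameters: (aspect, head_ratio, n_legs, tail, pattern, rgb)
_SPECIES = {
    0: (2.6, 0.30, 4, True,  "spots",   (150, 140, 110)),
    1: (1.3, 0.35, 2, False, "solid",   (60, 70, 110)),
    2: (1.7, 0.32, 4, False, "solid",   (150, 95, 60)),
    3: (1.5, 0.30, 4, False, "spots",   (120, 95, 65)),
    4: (2.1, 0.28, 4, True,  "stripes", (130, 125, 115)),
    5: (1.2, 0.42, 2, False, "solid",   (140, 115, 90)),
    6: (1.4, 0.38, 2, True,  "stripes", (90, 80, 75)),
}


def _scene_rng(spec: SceneSpec):
    return np.random.default_rng(np.random.SeedSequence([spec.seed, spec.class_id]))


def scene_geometry(spec: SceneSpec):
    """Normalized object geometry for a scene — pure function of the spec.

    Returns a list of dicts with the silhouette parts (normalized to the
    unit square) and the exact tight bounding box of their union.
    """
    rng = _scene_rng(spec)
    aspect, head_ratio, n_legs, tail, pattern, rgb = _SPECIES[spec.class_id % NUM_CLASSES]
    W, H = spec.width, spec.height
    objects = []
    for _ in range(spec.n_objects):
        placed = False
        for _attempt in range(50):
            size = rng.uniform(*spec.scale_range)   # target long side / min dim
            a = aspect * rng.uniform(0.9, 1.1)
            flip = bool(rng.integers(2))
            sgn = -1 if flip else 1
            # silhouette in local isotropic units; body half-length = 1
            b = 1.0 / a                              # body half-height
            rh = head_ratio
            parts_u = {"body": (0.0, 0.0, 1.0, b),
                       "head": (sgn * (1.0 + 0.4 * rh), -0.6 * b - 0.2 * rh, rh, rh)}
            legs_u = []
            for i in range(n_legs):
                frac = -0.7 + 1.4 * (i / max(n_legs - 1, 1))
                legs_u.append((frac * 0.8, b, 0.06 + 0.1 * rh, 1.1 * b))
            if tail:
                parts_u["tail"] = (-sgn * 1.05, -0.3 * b, 0.7 * rh, 0.5 * rh)
            xs, ys = [], []
            for ex, ey, rx, ry in parts_u.values():
                xs += [ex - rx, ex + rx]
                ys += [ey - ry, ey + ry]
            for lx, ly, lw_, ll in legs_u:
                xs += [lx - lw_, lx + lw_]
                ys += [ly, ly + ll]
            ux0, ux1, uy0, uy1 = min(xs), max(xs), min(ys), max(ys)
            # pixel scale so the silhouette's long side equals the target
            L = size * min(W, H)
            p = L / max(ux1 - ux0, uy1 - uy0)
            tw, th = p * (ux1 - ux0) / W, p * (uy1 - uy0) / H
            if tw >= 0.95 or th >= 0.95:
                continue
            ox = rng.uniform(0.02, 0.98 - tw) - p * ux0 / W
            oy = rng.uniform(0.02, 0.98 - th) - p * uy0 / H

            def to_norm(ex, ey, rx, ry):
                return (ox + p * ex / W, oy + p * ey / H, p * rx / W, p * ry / H)

            parts = {k: to_norm(*v) for k, v in parts_u.items()}
            parts["legs"] = [(ox + p * lx / W, oy + p * ly / H,
                              p * lw_ / W, p * ll / H) for lx, ly, lw_, ll in legs_u]
            x0 = ox + p * ux0 / W
            y0 = oy + p * uy0 / H
            objects.append({"parts": parts, "pattern": pattern, "rgb": rgb,
                            "bbox_norm": (x0, y0, p * (ux1 - ux0) / W,
                                          p * (uy1 - uy0) / H)})
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place object after bounded retries")
    return objects


def generate_scene(spec: SceneSpec, render_size: Optional[Tuple[int, int]] = None):
    """Render a scene; returns ``(image_uint8_HWC, [CocoAnnotation])``.

    Reproducible: identical specs yield byte-identical output.  The
    annotation boxes are the analytic silhouette bounds (tight to within
    pixel quantization of the rendered mask).
    """
    W, H = render_size if render_size is not None else (spec.width, spec.height)
    rng = _scene_rng(spec)
    objects = scene_geometry(spec)

    # background: layered integer value-noise (woodland / scrub clutter)
    base = np.array([74, 82, 58], dtype=np.int64)
    img = np.empty((H, W, 3), dtype=np.int64)
    img[:] = base
    bg_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    for block in (16, 4):
        hh, ww = max(H // block, 1), max(W // block, 1)
        coarse = bg_rng.integers(-28 // (1 if block == 16 else 2),
                                 28 // (1 if block == 16 else 2),
                                 size=(hh, ww, 3))
        up = np.repeat(np.repeat(coarse, -(-H // hh), axis=0), -(-W // ww), axis=1)
        img += up[:H, :W]

    yy = (np.arange(H)[:, None] + 0.5) / H
    xx = (np.arange(W)[None, :] + 0.5) / W

    def ellipse_mask(ex, ey, ax, ay):
        return ((xx - ex) / max(ax, 1e-9)) ** 2 + ((yy - ey) / max(ay, 1e-9)) ** 2 <= 1.0

    annotations = []
    for obj in objects:
        parts = obj["parts"]
        mask = ellipse_mask(*parts["body"])
        mask |= ellipse_mask(*parts["head"])
        for lx, ly, lw_, ll in parts["legs"]:
            mask |= (np.abs(xx - lx) <= lw_) & (yy >= ly) & (yy <= ly + ll)
        if "tail" in parts:
            mask |= ellipse_mask(*parts["tail"])
        color = np.array(obj["rgb"], dtype=np.int64)
        coat = np.empty((H, W, 3), dtype=np.int64)
        coat[:] = color
        if obj["pattern"] == "stripes":
            stripes = np.broadcast_to(
                ((xx * W // max(W // 40, 2)).astype(np.int64) % 2) == 0, (H, W))
            coat[stripes] = color * 2 // 3
        elif obj["pattern"] == "spots":
            gx = (xx * W // max(W // 28, 2)).astype(np.int64)
            gy = (yy * H // max(H // 28, 2)).astype(np.int64)
            spots = ((gx + 3 * gy) % 4) == 0
            coat[spots] = color * 3 // 5
        img[mask] = coat[mask]
        x0, y0, bw_, bh_ = obj["bbox_norm"]
        annotations.append(CocoAnnotation(0, W, H, spec.class_id,
                                          (x0 * W, y0 * H, bw_ * W, bh_ * H)))

    if spec.illumination == "night":
        gray = img.sum(axis=2) // 3
        img = (img + 3 * gray[..., None]) // 4      # desaturate
        img = img * 2 // 5                          # darken

    if spec.degradation == "blur":
        img = _box_blur(img)
    elif spec.degradation == "noise":
        noise = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 104729])).integers(-18, 19, size=img.shape)
        img = img + noise
    elif spec.degradation == "overexposure":
        img = img * 2

    return np.clip(img, 0, 255).astype(np.uint8), annotations


def _box_blur(img):
    p = np.pad(img, ((1, 1), (1, 1), (0, 0)), mode="edge").astype(np.int64)
    acc = np.zeros_like(img, dtype=np.int64)
    for dy in range(3):
        for dx in range(3):
            acc += p[dy:dy + img.shape[0], dx:dx + img.shape[1]]
    return acc // 9


# ---------------------------------------------------------------------------
# Dataset records, split, augmentation expansion
# ---------------------------------------------------------------------------

@dataclass
class ImageRecord:
    """One dataset image: a renderable scene plus labels (lazy pixels)."""

    image_id: int
    scene: SceneSpec
    labels: List[YoloLabel]
    augmentation: str = "none"


def make_dataset(class_counts=DEFAULT_CLASS_COUNTS, seed=0,
                 night_fraction=0.35, degraded_fraction=0.3,
                 n_objects=1, scale_range=(0.12, 0.45)):
    """Build the synthetic camera-trap dataset manifest, per class."""
    rng = np.random.default_rng(seed)
    by_class: Dict[int, List[ImageRecord]] = {}
    image_id = 0
    for cls, count in enumerate(class_counts):
        records = []
        for _ in range(count):
            w, h = RESOLUTIONS[rng.integers(len(RESOLUTIONS))]
            illum = "night" if rng.random() < night_fraction else "day"
            if rng.random() < degraded_fraction:
                degr = ("blur", "noise", "overexposure")[rng.integers(3)]
            else:
                degr = "none"
            spec = SceneSpec(w, h, cls, n_objects, illum, degr, scale_range,
                             seed=int(rng.integers(2 ** 31)))
            labels = [YoloLabel(cls, o["bbox_norm"][0] + o["bbox_norm"][2] / 2,
                                o["bbox_norm"][1] + o["bbox_norm"][3] / 2,
                                o["bbox_norm"][2], o["bbox_norm"][3])
                      for o in scene_geometry(spec)]
            records.append(ImageRecord(image_id, spec, labels))
            image_id += 1
        by_class[cls] = records
    return by_class


def split_dataset(images_by_class: Dict[int, list], ratios=(0.8, 0.1, 0.1), seed=0):
    """Per-class train/val/test split.

    Sizes per class of ``n`` images: ``val = round(r_val * n)``,
    ``test = floor(r_test * n)``, train takes the remainder — deterministic
    given the seed, no image lands in two splits.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in sorted(images_by_class):
        items = list(images_by_class[cls])
        n = len(items)
        if 0 < n < 3 and ratios[1] > 0:
            warnings.warn(f"class {cls} has only {n} images; all assigned to train")
            train.extend(items)
            continue
        order = rng.permutation(n)
        n_val = int(round(ratios[1] * n))
        n_test = int(ratios[2] * n)
        val.extend(items[i] for i in order[:n_val])
        test.extend(items[i] for i in order[n_val:n_val + n_test])
        train.extend(items[i] for i in order[n_val + n_test:])
    return train, val, test


def flip_labels(labels: Sequence[YoloLabel]) -> List[YoloLabel]:
    return [YoloLabel(l.cls, 1.0 - l.cx, l.cy, l.w, l.h) for l in labels]


def expand_with_augmentation(records: Sequence[ImageRecord], seed=0):
    """Each image gains one flipped, one HSV-jittered and one noise/blur
    variant: output count is exactly 4x the input count."""
    out = []
    next_id = max((r.image_id for r in records), default=-1) + 1
    for r in records:
        out.append(r)
        for aug in AUGMENTATIONS:
            labels = flip_labels(r.labels) if aug == "flip" else list(r.labels)
            out.append(ImageRecord(next_id, r.scene, labels, augmentation=aug))
            next_id += 1
    return out


def hsv_jitter(img, rng, gains=(0.015, 0.7, 0.4)):
    """Random hue/saturation/value gains (fractional), uint8 in/out."""
    img = img.astype(np.float64) / 255.0
    mx = img.max(axis=2)
    mn = img.min(axis=2)
    v = mx
    s = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-9), 0.0)
    gh, gs, gv = (1.0 + g * rng.uniform(-1, 1) for g in gains)
    v = np.clip(v * gv, 0, 1)
    s = np.clip(s * gs, 0, 1)
    # keep hue via channel proportions; rebuild from scaled s, v
    span = np.maximum(mx - mn, 1e-9)
    rel = (img - mn[..., None]) / span[..., None]
    new_mx = v
    new_mn = v * (1 - s)
    out = new_mn[..., None] + rel * (new_mx - new_mn)[..., None]
    # hue gain: roll channel weights slightly
    if abs(gh - 1.0) > 1e-9:
        shift = (gh - 1.0)
        out = np.stack([
            out[..., 0] * (1 - abs(shift)) + out[..., 1] * max(shift, 0) - out[..., 2] * min(shift, 0),
            out[..., 1],
            out[..., 2] * (1 - abs(shift)) + out[..., 1] * abs(shift) * 0.5,
        ], axis=2)
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)


def materialize(record: ImageRecord, render_size=None):
    """Render an image record (scene + augmentation) to pixels."""
    img, _ = generate_scene(record.scene, render_size=render_size)
    rng = np.random.default_rng(np.random.SeedSequence([record.scene.seed, record.image_id]))
    aug = record.augmentation
    if aug == "flip":
        img = img[:, ::-1].copy()
    elif aug == "hsv":
        img = hsv_jitter(img, rng)
    elif aug == "noise":
        if rng.random() < 0.5:
            img = np.clip(img.astype(np.int64) +
                          rng.integers(-20, 21, size=img.shape), 0, 255).astype(np.uint8)
        else:
            img = np.clip(_box_blur(img.astype(np.int64)), 0, 255).astype(np.uint8)
    return img, record.labels


def _nearest_resize(img, out_h, out_w):
    h, w = img.shape[:2]
    ys = (np.arange(out_h) * h) // out_h
    xs = (np.arange(out_w) * w) // out_w
    return img[ys][:, xs]


def mosaic_combine(images_with_labels, seed=0, out_size=640, min_visibility=0.25,
                   split_point=None):
    """2x2 mosaic collage with transformed, clipped labels.

    ``images_with_labels`` is four ``(image, [YoloLabel])`` pairs.  Boxes
    whose visible area after clipping falls below ``min_visibility`` of the
    (scaled) original are dropped.
    """
    if len(images_with_labels) != 4:
        raise ValueError("mosaic needs exactly four labelled images")
    rng = np.random.default_rng(seed)
    S = out_size
    if split_point is None:
        sx = int(rng.uniform(0.25, 0.75) * S)
        sy = int(rng.uniform(0.25, 0.75) * S)
    else:
        sx, sy = split_point
    canvas = np.zeros((S, S, 3), dtype=np.uint8)
    regions = [(0, 0, sx, sy), (sx, 0, S - sx, sy),
               (0, sy, sx, S - sy), (sx, sy, S - sx, S - sy)]
    labels_out = []
    for (img, labels), (ox, oy, rw, rh) in zip(images_with_labels, regions):
        if rw <= 0 or rh <= 0:
            continue
        canvas[oy:oy + rh, ox:ox + rw] = _nearest_resize(img, rh, rw)
        for l in labels:
            # label in canvas pixels
            cx, cy = ox + l.cx * rw, oy + l.cy * rh
            w, h = l.w * rw, l.h * rh
            x0, y0 = max(cx - w / 2, 0), max(cy - h / 2, 0)
            x1, y1 = min(cx + w / 2, S), min(cy + h / 2, S)
            if x1 <= x0 or y1 <= y0:
                continue
            if (x1 - x0) * (y1 - y0) < min_visibility * w * h:
                continue
            labels_out.append(YoloLabel(l.cls, (x0 + x1) / 2 / S, (y0 + y1) / 2 / S,
                                        (x1 - x0) / S, (y1 - y0) / S))
    return canvas, labels_out
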