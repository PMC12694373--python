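"""Seeded synthetic leaf-lesion detection imagery and annotation IO.

Real leaf-disease corpora come in two flavours: *clean* single-leaf images on
a plain laboratory background, and *cluttered* multi-leaf field scenes with
variable lighting and distractor foliage.  The generator emulates both at a
configurable scale: leaves are rendered as green ellipses with per-category
lesion blobs (category-coded hue, blob count and size), every leaf yields
exactly one axis-aligned bounding box, and everything is reproducible from a
single seed.  Datasets can be written to disk as PNG images plus COCO JSON
and YOLO txt annotations.

The augmentation set mirrors common practice for this imagery — Gaussian
blur, brightness scaling, rotation and horizontal flipping — with exact box
transforms (flips and 90-degree rotations permute coordinates exactly;
arbitrary-angle rotation replaces a box by the axis-aligned hull of its
rotated corners, clipped to the frame).  Splitting always happens *before*
augmentation so no augmented variant of a test image can leak into training.

Salt noise sets a seeded Bernoulli(p) fraction of pixel positions to the
maximum intensity, matching the robustness protocol of stepping p from 0 to
0.25 in increments of 0.025.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imbalance import DatasetIndex

__all__ = [
    "DetectionSample", "SceneSpec", "generate_dataset", "render_sample",
    "augment", "salt_noise", "split_then_augment",
    "write_coco", "read_coco", "write_yolo", "read_yolo",
]


@dataclass
class DetectionSample:
    """One image with axis-aligned boxes (half-open, 0-based) and labels."""

    image: np.ndarray                 # (H, W, 3) uint8
    boxes: list                       # [(x_min, y_min, x_max, y_max), ...]
    labels: list                      # category ids, parallel to boxes
    sample_id: str = ""
    source_id: str = ""               # original id for augmented variants

    def __post_init__(self):
        h, w = self.image.shape[:2]
        if len(self.boxes) != len(self.labels):
            raise ValueError("boxes and labels must be parallel")
        for b in self.boxes:
            x0, y0, x1, y1 = b
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"box {b} outside image bounds ({w}x{h})")
        if not self.source_id:
            self.source_id = self.sample_id


@dataclass(frozen=True)
class SceneSpec:
    """Rendering recipe for one synthetic dataset.

    ``clutter`` selects the background style: ``"clean"`` (near-uniform light
    backdrop, one leaf by default) or ``"cluttered"`` (distractor foliage,
    gradients and speckle, several leaves).  Lesion style per category is
    derived deterministically from the category id, so a category looks the
    same across images and seeds.
    """

    n_categories: int = 9
    clutter: str = "clean"
    image_size: tuple = (160, 160)
    leaves_per_image: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.clutter not in ("clean", "cluttered"):
            raise ValueError("clutter must be 'clean' or 'cluttered'")
        if min(self.image_size) <= 0:
            raise ValueError("image size must be positive")
        if self.leaves_per_image is None:
            rng = (1, 1) if self.clutter == "clean" else (2, 4)
            object.__setattr__(self, "leaves_per_image", rng)


def _category_style(category: int):
    """Deterministic lesion style: (rgb colour, blob count, blob radius frac)."""
    rng = np.random.default_rng(10_000 + category)
    hue = rng.uniform(0, 1)
    # category-coded colours away from leaf green
    base = np.array([0.55 + 0.45 * np.cos(6.28 * hue),
                     0.25 + 0.2 * np.sin(6.28 * hue + 2.0),
                     0.2 + 0.4 * np.abs(np.sin(6.28 * hue + 4.0))])
    colour = (np.clip(base, 0, 1) * 255).astype(np.uint8)
    n_blobs = 2 + category % 4
    radius = 0.06 + 0.02 * (category % 3)
    return colour, n_blobs, radius


def _draw_ellipse(img, cy, cx, ry, rx, colour, angle=0.0):
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    mask = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    img[mask] = colour
    return mask


def render_sample(spec: SceneSpec, category_plan, rng: np.random.Generator,
                  sample_id: str = "") -> DetectionSample:
    """Render one scene containing the categories in ``category_plan``."""
    h, w = spec.image_size
    img = np.zeros((h, w, 3), dtype=np.uint8)
    if spec.clutter == "clean":
        img[...] = np.array([235, 235, 228], dtype=np.uint8)
        img = np.clip(img.astype(np.int16)
                      + rng.integers(-6, 7, size=(h, w, 1)), 0, 255).astype(np.uint8)
    else:
        # gradient sky/soil plus distractor foliage and speckle
        grad = np.linspace(60, 140, h)[:, None, None]
        img = (grad + np.array([10.0, 30.0, 5.0])).astype(np.uint8)
        img = np.ascontiguousarray(np.broadcast_to(img, (h, w, 3)).copy())
        for _ in range(rng.integers(4, 9)):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            ry, rx = rng.uniform(0.05, 0.2) * h, rng.uniform(0.05, 0.2) * w
            shade = rng.integers(40, 110)
            _draw_ellipse(img, cy, cx, ry, rx,
                          np.array([shade // 3, shade, shade // 4], dtype=np.uint8),
                          angle=rng.uniform(0, np.pi))
        speck = rng.integers(-18, 19, size=(h, w, 1))
        img = np.clip(img.astype(np.int16) + speck, 0, 255).astype(np.uint8)

    boxes, labels = [], []
    for category in category_plan:
        for _attempt in range(50):
            ry = rng.uniform(0.12, 0.22) * h
            rx = rng.uniform(0.12, 0.22) * w
            cy = rng.uniform(ry + 1, h - ry - 1)
            cx = rng.uniform(rx + 1, w - rx - 1)
            angle = rng.uniform(0, np.pi)
            x0 = int(np.floor(cx - rx))
            y0 = int(np.floor(cy - ry))
            x1 = int(np.ceil(cx + rx)) + 1
            y1 = int(np.ceil(cy + ry)) + 1
            x0, y0 = max(0, x0), max(0, y0)
            x1, y1 = min(w, x1), min(h, y1)
            new = (x0, y0, x1, y1)
            if all(_box_iou(new, b) < 0.25 for b in boxes):
                break
        leaf_green = np.array([30 + rng.integers(0, 25),
                               120 + rng.integers(0, 60),
                               30 + rng.integers(0, 20)], dtype=np.uint8)
        _draw_ellipse(img, cy, cx, ry, rx, leaf_green, angle)
        colour, n_blobs, rad = _category_style(category)
        for _ in range(n_blobs):
            t = rng.uniform(0, 2 * np.pi)
            rr = rng.uniform(0, 0.6)
            by = cy + rr * ry * np.sin(t)
            bx = cx + rr * rx * np.cos(t)
            br = rad * min(ry, rx) / 0.15
            _draw_ellipse(img, by, bx, max(1.5, br), max(1.5, br), colour)
        boxes.append(new)
        labels.append(int(category))
    return DetectionSample(image=img, boxes=boxes, labels=labels,
                           sample_id=sample_id)


def _box_iou(a, b):
    iw = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    ih = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = iw * ih
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def generate_dataset(spec: SceneSpec, n_images: int | None = None,
                     category_counts: dict | None = None,
                     out_dir: str | Path | None = None):
    """Generate a dataset; returns (samples, DatasetIndex).

    Either give ``n_images`` (categories drawn uniformly) or
    ``category_counts`` mapping category -> number of images whose *first*
    leaf carries that category.  With ``out_dir`` set, PNG images, a COCO
    JSON and YOLO txt files are written (byte-identical for identical seeds).
    """
    if category_counts is not None:
        plan = [c for c, n in sorted(category_counts.items()) for _ in range(n)]
    elif n_images is not None:
        plan = [i % spec.n_categories for i in range(n_images)]
    else:
        raise ValueError("give n_images or category_counts")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(plan))
    samples = []
    for k, idx in enumerate(order):
        primary = plan[idx]
        lo, hi = spec.leaves_per_image
        n_leaves = int(rng.integers(lo, hi + 1))
        extras = rng.integers(0, spec.n_categories, size=max(0, n_leaves - 1))
        cats = [primary] + [int(e) for e in extras]
        samples.append(render_sample(spec, cats, rng, sample_id=f"img_{k:05d}"))
    index = DatasetIndex({
        c: [s.sample_id for s in samples if s.labels and s.labels[0] == c]
        for c in sorted({s.labels[0] for s in samples if s.labels})})
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        from PIL import Image
        for s in samples:
            Image.fromarray(s.image).save(out_dir / "images" / f"{s.sample_id}.png")
        write_coco(samples, out_dir / "annotations.json",
                   n_categories=spec.n_categories)
        write_yolo(samples, out_dir / "labels")
    return samples, index


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

def _rotate_boxes_90(boxes, w):
    """One counter-clockwise quarter turn: (x, y) -> (y, w - x)."""
    return [(y0, w - x1, y1, w - x0) for (x0, y0, x1, y1) in boxes]


def _rotate_boxes_free(boxes, angle_deg, w, h):
    """Axis-aligned hull of each box's rotated corners, clipped to the frame."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    cx, cy = w / 2.0, h / 2.0
    out = []
    for (x0, y0, x1, y1) in boxes:
        xs = np.array([x0, x1, x0, x1]) - cx
        ys = np.array([y0, y0, y1, y1]) - cy
        xr = c * xs + s * ys + cx
        yr = -s * xs + c * ys + cy
        nx0 = float(np.clip(xr.min(), 0, w))
        nx1 = float(np.clip(xr.max(), 0, w))
        ny0 = float(np.clip(yr.min(), 0, h))
        ny1 = float(np.clip(yr.max(), 0, h))
        out.append((nx0, ny0, nx1, ny1))
    return out


def augment(sample: DetectionSample, op: str, params: dict | None = None,
            seed: int | None = None) -> DetectionSample:
    """Apply one augmentation; boxes are transformed exactly.

    Supported ops: ``blur`` (Gaussian, ``sigma``), ``brightness`` (``factor``),
    ``rotate`` (``angle`` degrees; multiples of 90 are exact), ``hflip``.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    img = sample.image
    h, w = img.shape[:2]
    if op == "blur":
        sigma = params.get("sigma", 1.5)
        out = ndimage.gaussian_filter(img.astype(np.float64), (sigma, sigma, 0))
        return replace(sample, image=np.clip(out, 0, 255).astype(np.uint8),
                       boxes=list(sample.boxes),
                       sample_id=f"{sample.sample_id}+blur",
                       source_id=sample.source_id)
    if op == "brightness":
        factor = params.get("factor", rng.uniform(1.1, 1.4))
        out = np.clip(img.astype(np.float64) * factor, 0, 255).astype(np.uint8)
        return replace(sample, image=out, boxes=list(sample.boxes),
                       sample_id=f"{sample.sample_id}+bright",
                       source_id=sample.source_id)
    if op == "hflip":
        out = img[:, ::-1].copy()
        boxes = [(w - x1, y0, w - x0, y1) for (x0, y0, x1, y1) in sample.boxes]
        return replace(sample, image=out, boxes=boxes,
                       sample_id=f"{sample.sample_id}+hflip",
                       source_id=sample.source_id)
    if op == "rotate":
        angle = params.get("angle")
        if angle is None:
            angle = float(rng.uniform(-15.0, 15.0))
        if angle % 90 == 0:
            k = int(angle // 90) % 4
            out = np.ascontiguousarray(np.rot90(img, k))
            boxes = list(sample.boxes)
            width = w
            for _ in range(k):
                boxes = _rotate_boxes_90(boxes, width)
                width = h if width == w else w
            return replace(sample, image=out, boxes=boxes,
                           sample_id=f"{sample.sample_id}+rot{int(angle)}",
                           source_id=sample.source_id)
        out = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="nearest")
        boxes = _rotate_boxes_free(sample.boxes, angle, w, h)
        return replace(sample, image=np.clip(out, 0, 255).astype(np.uint8),
                       boxes=boxes,
                       sample_id=f"{sample.sample_id}+rot{angle:.1f}",
                       source_id=sample.source_id)
    raise ValueError(f"unknown augmentation op {op!r}")


def salt_noise(image: np.ndarray, p: float, seed: int | None = None) -> np.ndarray:
    """Set a seeded Bernoulli(p) fraction of pixel positions to maximum value.

    Pure salt (no pepper): selected pixels go to 255 across all channels.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"noise fraction must lie in [0, 1], got {p}")
    out = image.copy()
    if p == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(image.shape[:2]) < p
    out[mask] = np.iinfo(image.dtype).max if np.issubdtype(image.dtype, np.integer) else 1.0
    return out


def split_then_augment(samples, test_fraction: float, aug_plan, seed: int):
    """Split on original IDs first, then augment only the training split.

    ``aug_plan`` is a list of (op, params) pairs; each training original gains
    one variant per entry.  Returns (train_samples, test_samples); the test
    samples are the untouched originals.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(samples)
    n_test = int(np.floor(test_fraction * n + 0.5))
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    test = [samples[i] for i in range(n) if i in test_idx]
    train = [samples[i] for i in range(n) if i not in test_idx]
    augmented = list(train)
    for op, params in aug_plan:
        for s in train:
            augmented.append(augment(s, op, params,
                                     seed=int(rng.integers(0, 2**31 - 1))))
    return augmented, test


# ---------------------------------------------------------------------------
# annotation IO
# ---------------------------------------------------------------------------

def write_coco(samples, path: str | Path, n_categories: int = 9) -> None:
    """Write COCO-dialect JSON (bbox = [x, y, width, height])."""
    images, annotations = [], []
    ann_id = 1
    for i, s in enumerate(samples, start=1):
        h, w = s.image.shape[:2]
        images.append({"id": i, "file_name": f"{s.sample_id}.png",
                       "width": w, "height": h})
        for box, label in zip(s.boxes, s.labels):
            x0, y0, x1, y1 = box
            annotations.append({
                "id": ann_id, "image_id": i, "category_id": int(label),
                "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                "area": float((x1 - x0) * (y1 - y0)), "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": c, "name": f"category_{c}"}
                       for c in range(n_categories)],
    }
    Path(path).write_text(json.dumps(doc, indent=None, sort_keys=True))


def read_coco(path: str | Path):
    """Read COCO JSON; returns (boxes_by_image, labels_by_image, meta)."""
    doc = json.loads(Path(path).read_text())
    boxes: dict = {img["id"]: [] for img in doc["images"]}
    labels: dict = {img["id"]: [] for img in doc["images"]}
    for ann in doc["annotations"]:
        x, y, bw, bh = ann["bbox"]
        boxes[ann["image_id"]].append((x, y, x + bw, y + bh))
        labels[ann["image_id"]].append(ann["category_id"])
    return boxes, labels, doc


def write_yolo(samples, directory: str | Path) -> None:
    """Write one YOLO txt per sample: ``class cx cy w h`` normalised."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in samples:
        h, w = s.image.shape[:2]
        lines = []
        for box, label in zip(s.boxes, s.labels):
            x0, y0, x1, y1 = box
            cx, cy = (x0 + x1) / 2.0 / w, (y0 + y1) / 2.0 / h
            bw, bh = (x1 - x0) / w, (y1 - y0) / h
            lines.append(f"{int(label)} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
        (directory / f"{s.sample_id}.txt").write_text("\n".join(lines) + "\n")


def read_yolo(path: str | Path, image_size: tuple):
    """Read one YOLO txt back into pixel boxes for the given (H, W)."""
    h, w = image_size
    boxes, labels = [], []
    text = Path(path).read_text().strip()
    if not text:
        return boxes, labels
    for line in text.splitlines():
        parts = line.split()
        label = int(parts[0])
        cx, cy, bw, bh = (float(v) for v in parts[1:5])
        boxes.append(((cx - bw / 2) * w, (cy - bh / 2) * h,
                      (cx + bw / 2) * w, (cy + bh / 2) * h))
        labels.append(label)
    return boxes, labels
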