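"""A small trainable detector assembling the package's components.

The harness exists to exercise the blocks end-to-end at desk scale: a compact
convolutional backbone whose two deepest stages carry MSDRM blocks, the MSFPN
neck, and a minimal anchor-based dense head per detection scale (strides 8,
16, 32).  Classification uses the adaptive focal loss with IoU-aware targets;
box regression is a squared error on encoded offsets.  The full transformer
encoder/decoder of the base detector is deliberately out of scope — the dense
head is just enough machinery to train and evaluate the components.

Target assignment is per-location max-IoU: each location owns one square
anchor (side ``3 x stride``); anchors with IoU >= 0.5 against a ground truth
are positive, and the best anchor for every ground truth is forced positive
so no object goes unsupervised.  The positive quality target is the IoU of
the *decoded predicted* box with its matched ground truth, recomputed every
step and detached, per the IoU-aware varifocal convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .afl import AFLState, QualityTargets, afl_batch_loss, update_auto_iou
from .metrics import Detection, box_iou_matrix, nms
from .msdrm import MSDRM, ConvBNAct
from .msfpn import MSFPN, PyramidLevels
from .nn.autograd import Tensor, concat
from .nn.layers import SGD, Conv2d, Module, count_parameters

__all__ = ["DetectorConfig", "Detector", "build_model", "train_smoke",
           "detect", "recall_by_class", "default_config"]

STRIDES = (8, 16, 32)


@dataclass(frozen=True)
class DetectorConfig:
    num_classes: int = 9
    image_size: int = 64
    widths: tuple = (8, 16, 24, 32)      # stem/stride-8, 8, 16, 32 stage widths
    neck_width: int = 16
    kernel_set: tuple = (5, 7, 9, 11)
    use_msdrm: bool = True
    anchor_scale: float = 3.0            # anchor side = anchor_scale * stride
    afl: AFLState = AFLState()
    seed: int = 0

    def __post_init__(self):
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")
        if len(self.widths) != 4:
            raise ValueError("expected 4 stage widths")


def default_config(**overrides) -> DetectorConfig:
    return dataclasses.replace(DetectorConfig(), **overrides)


class Backbone(Module):
    """Four downsampling stages; MSDRM replaces the residual block in the
    deepest two stages when enabled."""

    def __init__(self, widths, use_msdrm=True, rng=None):
        super().__init__()
        w0, w1, w2, w3 = widths
        self.stem = ConvBNAct(3, w0, 3, stride=2, rng=rng)       # stride 2
        self.stage1 = ConvBNAct(w0, w0, 3, stride=2, rng=rng)    # stride 4
        self.stage2 = ConvBNAct(w0, w1, 3, stride=2, rng=rng)    # stride 8
        self.stage3_down = ConvBNAct(w1, w2, 3, stride=2, rng=rng)   # stride 16
        self.stage4_down = ConvBNAct(w2, w3, 3, stride=2, rng=rng)   # stride 32
        self.stage3_block = MSDRM(w2, rng=rng) if use_msdrm else ConvBNAct(w2, w2, 3, rng=rng)
        self.stage4_block = MSDRM(w3, rng=rng) if use_msdrm else ConvBNAct(w3, w3, 3, rng=rng)

    def forward(self, x):
        x = self.stage2(self.stage1(self.stem(x)))
        c2 = x
        c3 = self.stage3_block(self.stage3_down(c2))
        c4 = self.stage4_block(self.stage4_down(c3))
        return c2, c3, c4


class Detector(Module):
    def __init__(self, config: DetectorConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        w0, w1, w2, w3 = config.widths
        self.backbone = Backbone(config.widths, config.use_msdrm, rng=rng)
        self.neck = MSFPN((w1, w2, w3), width=config.neck_width,
                          kernel_set=config.kernel_set, rng=rng)
        nc = config.num_classes
        self.heads = [Conv2d(config.neck_width, nc + 4, 1, rng=rng)
                      for _ in STRIDES]

    def forward(self, images):
        """images: (N, 3, H, W) in [0, 1]. Returns one (N, nc+4, h, w) map
        per stride."""
        t = images if isinstance(images, Tensor) else Tensor(images)
        c2, c3, c4 = self.backbone(t)
        p8, p16, p32 = self.neck(PyramidLevels(c2, c3, c4))
        return [head(p) for head, p in zip(self.heads, (p8, p16, p32))]

    def parameter_count(self) -> int:
        return count_parameters(self)


def build_model(config: DetectorConfig | dict | None = None, **overrides) -> Detector:
    """Build the detector from a config object, a plain dict, or keywords."""
    if config is None:
        config = DetectorConfig(**overrides)
    elif isinstance(config, dict):
        cfg = dict(config)
        afl = cfg.pop("afl", None)
        if isinstance(afl, dict):
            afl = AFLState(**{{"lambda": "lam"}.get(k, k): v for k, v in afl.items()})
        if afl is not None:
            cfg["afl"] = afl
        for key in ("widths", "kernel_set"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        config = DetectorConfig(**{**cfg, **overrides})
    return Detector(config)


# ---------------------------------------------------------------------------
# anchors and target assignment
# ---------------------------------------------------------------------------

def _anchors_for(image_size: int, anchor_scale: float):
    """Per-stride anchor centers and boxes: list of (centers, boxes, base)."""
    out = []
    for s in STRIDES:
        n = image_size // s
        cy, cx = np.mgrid[0:n, 0:n]
        cx = (cx + 0.5) * s
        cy = (cy + 0.5) * s
        base = anchor_scale * s
        boxes = np.stack([cx - base / 2, cy - base / 2,
                          cx + base / 2, cy + base / 2], axis=-1).reshape(-1, 4)
        centers = np.stack([cx, cy], axis=-1).reshape(-1, 2)
        out.append((centers, boxes, base))
    return out


def assign_targets(gt_boxes, gt_labels, anchors, num_classes,
                   pos_iou: float = 0.5):
    """Max-IoU assignment over the concatenated anchor set of one image.

    Returns (matched_gt index per anchor, -1 for negatives).  The best anchor
    of every ground truth is forced positive.
    """
    all_boxes = np.concatenate([a[1] for a in anchors], axis=0)
    n_anchor = all_boxes.shape[0]
    match = np.full(n_anchor, -1, dtype=int)
    if len(gt_boxes) == 0:
        return match
    ious = box_iou_matrix(all_boxes, np.asarray(gt_boxes, dtype=np.float64))
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(n_anchor), best_gt]
    match[best_iou >= pos_iou] = best_gt[best_iou >= pos_iou]
    # guarantee one positive per object
    forced = ious.argmax(axis=0)
    match[forced] = np.arange(len(gt_boxes))
    return match


def _decode(pred: np.ndarray, centers: np.ndarray, base: float, stride: int):
    """Decode (n, 4) offset predictions into pixel boxes."""
    tx, ty, tw, th = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    cx = centers[:, 0] + tx * stride
    cy = centers[:, 1] + ty * stride
    bw = base * np.exp(np.clip(tw, -4, 4))
    bh = base * np.exp(np.clip(th, -4, 4))
    return np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=-1)


def _encode(gt: np.ndarray, centers: np.ndarray, base: float, stride: int):
    cx = (gt[:, 0] + gt[:, 2]) / 2
    cy = (gt[:, 1] + gt[:, 3]) / 2
    bw = np.maximum(gt[:, 2] - gt[:, 0], 1e-3)
    bh = np.maximum(gt[:, 3] - gt[:, 1], 1e-3)
    return np.stack([(cx - centers[:, 0]) / stride,
                     (cy - centers[:, 1]) / stride,
                     np.log(bw / base), np.log(bh / base)], axis=-1)


def compute_loss(model: Detector, images, gt_per_image, state: AFLState,
                 loss_mode: str = "afl", box_weight: float = 1.0):
    """One forward pass and loss over a batch.

    ``gt_per_image`` is a list of (boxes, labels) tuples.  Returns
    (total_loss Tensor, iou_batch or None, diagnostics dict).
    ``loss_mode='vfl'`` drops the modulating weight (plain varifocal loss) as
    the ablation baseline.
    """
    cfg = model.config
    nc = cfg.num_classes
    outputs = model(images)
    N = images.shape[0]
    anchors = _anchors_for(cfg.image_size, cfg.anchor_scale)
    counts = [a[1].shape[0] for a in anchors]
    centers = np.concatenate([a[0] for a in anchors])
    bases = np.concatenate([np.full(c, a[2]) for c, a in zip(counts, anchors)])
    strides = np.concatenate([np.full(c, s) for c, s in zip(counts, STRIDES)])

    # per-stride flat maps are ordered (image, y, x); regroup per image
    cls_parts, box_parts = [], []
    for out in outputs:
        n, C, H, W = out.shape
        flat = out.transpose((0, 2, 3, 1)).reshape(n, H * W, C)
        cls_parts.append(flat[:, :, :nc])
        box_parts.append(flat[:, :, nc:])
    cls_logits = concat(cls_parts, axis=1)        # (N, A, nc)
    box_pred = concat(box_parts, axis=1)          # (N, A, 4)

    quality = np.zeros((N, sum(counts), nc))
    pos_mask = np.zeros((N, sum(counts)), dtype=bool)
    box_targets = np.zeros((N, sum(counts), 4))
    pos_ious = []
    for n in range(N):
        boxes, labels = gt_per_image[n]
        match = assign_targets(boxes, labels, anchors, nc)
        pos = match >= 0
        if not pos.any():
            continue
        pos_mask[n] = pos
        gt = np.asarray(boxes, dtype=np.float64)[match[pos]]
        lab = np.asarray(labels, dtype=int)[match[pos]]
        dec = _decode(box_pred.data[n][pos], centers[pos],
                      bases[pos], strides[pos])
        q = box_iou_matrix(dec, gt).diagonal() if len(gt) else np.zeros(0)
        quality[n, np.where(pos)[0], lab] = q
        box_targets[n][pos] = _encode(gt, centers[pos], bases[pos], strides[pos])
        pos_ious.append(q)

    iou_batch = float(np.mean(np.concatenate(pos_ious))) if pos_ious else None
    cls_flat = cls_logits.reshape(-1)
    q_flat = quality.reshape(-1)
    if loss_mode == "afl":
        cls_loss = afl_batch_loss(
            QualityTargets(cls_flat, q_flat, iou_batch or 0.0), state)
    elif loss_mode == "vfl":
        from .afl import varifocal_loss
        cls_loss = varifocal_loss(cls_flat, q_flat, state.alpha, state.gamma).mean()
    else:
        raise ValueError(f"unknown loss_mode {loss_mode!r}")

    n_pos = int(pos_mask.sum())
    if n_pos:
        diff = box_pred - Tensor(box_targets)
        masked = diff * Tensor(pos_mask[:, :, None].astype(float))
        box_loss = (masked ** 2.0).sum() * (1.0 / (4 * n_pos))
    else:
        box_loss = Tensor(0.0)
    total = cls_loss * (float(cls_flat.shape[0]) / max(n_pos * nc, 1)) \
        + box_weight * box_loss
    return total, iou_batch, {"cls": cls_loss, "box": box_loss, "n_pos": n_pos}


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def train_smoke(model: Detector, samples, steps: int = 200, seed: int = 0,
                batch_size: int = 4, lr: float = 0.01, final_lr: float = 0.001,
                momentum: float = 0.9, weight_decay: float = 5e-4,
                loss_mode: str = "afl"):
    """Seeded SGD smoke training; returns the loss / auto_iou trajectory.

    The learning rate anneals linearly from ``lr`` to ``final_lr``.  A
    non-finite loss aborts with a diagnostic.  When a batch has no positive
    matches the previous step's batch IoU is reused for the auto_iou update.
    """
    rng = np.random.default_rng(seed)
    model.train()
    opt = SGD(model.parameters(), lr=lr, momentum=momentum,
              weight_decay=weight_decay)
    state = model.config.afl
    images = np.stack([s.image for s in samples]).astype(np.float64) / 255.0
    images = images.transpose(0, 3, 1, 2)
    gts = [(list(s.boxes), list(s.labels)) for s in samples]
    history = {"loss": [], "auto_iou": [], "iou_batch": [], "lr": []}
    last_iou = 0.0
    for step in range(steps):
        frac = step / max(steps - 1, 1)
        opt.lr = lr + (final_lr - lr) * frac
        idx = rng.choice(len(samples), size=min(batch_size, len(samples)),
                         replace=False)
        batch = images[idx]
        batch_gts = [gts[i] for i in idx]
        loss, iou_batch, _ = compute_loss(model, batch, batch_gts, state,
                                          loss_mode=loss_mode)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"training diverged at step {step}: loss={loss.data!r}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if iou_batch is None:
            iou_batch = last_iou
        last_iou = iou_batch
        state = update_auto_iou(state, iou_batch)
        history["loss"].append(float(loss.data))
        history["auto_iou"].append(state.auto_iou)
        history["iou_batch"].append(iou_batch)
        history["lr"].append(opt.lr)
    history["final_state"] = state
    return history


def detect(model: Detector, image: np.ndarray, score_threshold: float = 0.3,
           nms_iou: float = 0.5, image_id: int = 0):
    """Run inference on one HWC uint8 image; returns a list of Detections."""
    cfg = model.config
    was_training = model.training
    model.eval()
    x = image.astype(np.float64)[None].transpose(0, 3, 1, 2) / 255.0
    outputs = model(x)
    anchors = _anchors_for(cfg.image_size, cfg.anchor_scale)
    dets = []
    all_boxes, all_scores, all_labels = [], [], []
    for out, (centers, _aboxes, base), stride in zip(outputs, anchors, STRIDES):
        arr = out.data[0]
        nc = cfg.num_classes
        C, H, W = arr.shape
        flat = arr.transpose(1, 2, 0).reshape(-1, C)
        scores = 1.0 / (1.0 + np.exp(-flat[:, :nc]))
        boxes = _decode(flat[:, nc:], centers, base, stride)
        best = scores.max(axis=1)
        lab = scores.argmax(axis=1)
        keep = best >= score_threshold
        all_boxes.append(boxes[keep])
        all_scores.append(best[keep])
        all_labels.append(lab[keep])
    boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 4))
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    labels = np.concatenate(all_labels) if all_labels else np.zeros(0, dtype=int)
    for c in np.unique(labels):
        m = labels == c
        kept = nms(boxes[m], scores[m], nms_iou)
        for k in kept:
            b = boxes[m][k]
            dets.append(Detection(image_id=image_id, category_id=int(c),
                                  box=tuple(b), score=float(scores[m][k])))
    if was_training:
        model.train()
    return dets


def recall_by_class(model: Detector, samples, iou_threshold: float = 0.5,
                    score_threshold: float = 0.25) -> dict:
    """Fraction of ground-truth objects recovered, per category."""
    hits: dict = {}
    totals: dict = {}
    for i, s in enumerate(samples):
        dets = detect(model, s.image, score_threshold=score_threshold,
                      image_id=i)
        for box, label in zip(s.boxes, s.labels):
            totals[label] = totals.get(label, 0) + 1
            matched = any(
                d.category_id == label
                and box_iou_matrix(np.array(d.box)[None],
                                   np.array(box)[None])[0, 0] >= iou_threshold
                for d in dets)
            hits[label] = hits.get(label, 0) + int(matched)
    return {c: hits.get(c, 0) / totals[c] for c in totals}
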