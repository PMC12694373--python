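"""Adaptive focal loss (AFL) for IoU-aware classification under class imbalance.

AFL extends varifocal loss with two training-time mechanisms:

* a **decay factor** ``D_i = delta * (1 - exp(-i / lam))`` that rises smoothly
  from 0 towards ``delta`` over optimizer steps ``i``, and
* a **dynamic IoU threshold** ``auto_iou``, an exponential moving average of
  the batch mean IoU (smoothed by ``D_i``) floored at 0.2, that splits targets
  into three quality bands with piecewise modulating weights:

  - ``Truei <= auto_iou - 0.1``       -> weight 1.0 (low-quality, left alone)
  - ``auto_iou - 0.1 < Truei < auto_iou`` -> ``exp(1 - auto_iou)`` (boundary
    band, amplified to emphasise medium-quality samples)
  - ``Truei >= auto_iou``             -> ``exp(1 - Truei)`` (easy samples,
    progressively down-weighted)

The weights depend only on ground-truth quality, so they contribute no
gradient with respect to the predictions.  ``D_i`` enters *only* the
``auto_iou`` moving average; it never rescales the loss itself.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, bce_with_logits

__all__ = [
    "AFLState",
    "QualityTargets",
    "decay_factor",
    "update_auto_iou",
    "modulating_weight",
    "varifocal_loss",
    "afl_batch_loss",
]

IOU_FLOOR = 0.2


@dataclass(frozen=True)
class AFLState:
    """Mutable training state of the loss, advanced once per optimizer step.

    Attributes
    ----------
    i : int
        Number of completed auto_iou updates (optimizer steps).
    auto_iou, auto_iou_pre : float
        Current and previous dynamic IoU threshold, each in [0.2, 1].
    delta, lam : float
        Decay coefficient and decay-rate constant of ``D_i``.
    alpha, gamma : float
        Varifocal negative-sample scale and focusing exponent.
    """

    i: int = 0
    auto_iou: float = IOU_FLOOR
    auto_iou_pre: float = IOU_FLOOR
    delta: float = 0.999
    lam: float = 2000.0
    alpha: float = 0.75
    gamma: float = 2.0

    def __post_init__(self):
        if self.i < 0:
            raise ValueError("update count must be non-negative")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


def decay_factor(i: int, delta: float = 0.999, lam: float = 2000.0) -> float:
    """``D_i = delta * (1 - exp(-i / lam))``: 0 at step 0, -> delta as i grows."""
    if i < 0:
        raise ValueError("step count must be non-negative")
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    return float(delta * (1.0 - np.exp(-float(i) / float(lam))))


def update_auto_iou(state: AFLState, iou_batch: float) -> AFLState:
    """Advance the dynamic threshold by one optimizer step.

    ``auto_iou <- max(D_i * auto_iou_pre + (1 - D_i) * iou_batch, 0.2)`` where
    ``auto_iou_pre`` is the threshold of the previous completed update.
    """
    if not (0.0 <= iou_batch <= 1.0):
        raise ValueError(f"iou_batch must lie in [0, 1], got {iou_batch}")
    d = decay_factor(state.i, state.delta, state.lam)
    new = max(d * state.auto_iou + (1.0 - d) * float(iou_batch), IOU_FLOOR)
    return dataclasses.replace(state, i=state.i + 1,
                               auto_iou=new, auto_iou_pre=state.auto_iou)


def modulating_weight(true_quality, auto_iou: float):
    """Piecewise quality weight; a pure function of ground-truth quantities."""
    if not (IOU_FLOOR <= auto_iou <= 1.0):
        raise ValueError(f"auto_iou must lie in [{IOU_FLOOR}, 1], got {auto_iou}")
    t = np.asarray(true_quality, dtype=np.float64)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("true_quality must lie in [0, 1]")
    w = np.ones_like(t)
    mid = (t > auto_iou - 0.1) & (t < auto_iou)
    high = t >= auto_iou
    w[mid] = np.exp(1.0 - auto_iou)
    w[high] = np.exp(1.0 - t[high])
    if np.isscalar(true_quality) or np.ndim(true_quality) == 0:
        return float(w)
    return w


def varifocal_loss(pred_logit, true_quality, alpha: float = 0.75,
                   gamma: float = 2.0):
    """IoU-aware varifocal loss, element-wise, in logit space.

    ``[alpha * sigmoid(p)**gamma * (1 - q) + q] * BCEWithLogits(p, q)`` — the
    quality target ``q`` weights positives directly while negatives are scaled
    by ``alpha`` and focused by ``gamma``.  Accepts plain arrays (returns an
    array/float) or an autograd :class:`Tensor` of logits (returns a Tensor
    whose gradient flows only through the predictions).
    """
    q = np.asarray(true_quality, dtype=np.float64)
    if np.any(q < 0.0) or np.any(q > 1.0):
        raise ValueError("true_quality must lie in [0, 1]")
    if isinstance(pred_logit, Tensor):
        weight = pred_logit.sigmoid() ** gamma * Tensor(alpha * (1.0 - q)) + Tensor(q)
        return bce_with_logits(pred_logit, q) * weight
    x = np.asarray(pred_logit, dtype=np.float64)
    p = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    bce = np.maximum(x, 0.0) - x * q + np.log1p(np.exp(-np.abs(x)))
    out = (alpha * p ** gamma * (1.0 - q) + q) * bce
    if np.isscalar(pred_logit) or np.ndim(pred_logit) == 0:
        return float(out)
    return out


@dataclass
class QualityTargets:
    """One batch of IoU-aware classification targets.

    ``pred_logits`` are pre-sigmoid scores (array or Tensor); ``true_quality``
    holds the matched-IoU target per element (0 for negatives); ``iou_batch``
    is the mean IoU of the batch's positive matches, used by the caller to
    advance :func:`update_auto_iou` once per optimizer step.
    """

    pred_logits: object
    true_quality: np.ndarray
    iou_batch: float = 0.0

    def __post_init__(self):
        self.true_quality = np.asarray(self.true_quality, dtype=np.float64)
        if np.any(self.true_quality < 0.0) or np.any(self.true_quality > 1.0):
            raise ValueError("true_quality must lie in [0, 1]")
        if not (0.0 <= self.iou_batch <= 1.0):
            raise ValueError("iou_batch must lie in [0, 1]")


def afl_batch_loss(batch: QualityTargets, state: AFLState):
    """Mean of varifocal loss x modulating weight at the state's auto_iou.

    The decay factor never rescales this value; it only smooths the auto_iou
    update, which the training loop applies separately once per step.
    """
    if batch.true_quality.size == 0:
        raise ValueError("empty batch")
    w = modulating_weight(batch.true_quality, state.auto_iou)
    vfl = varifocal_loss(batch.pred_logits, batch.true_quality,
                         state.alpha, state.gamma)
    if isinstance(vfl, Tensor):
        return (vfl * Tensor(np.asarray(w))).mean()
    return float(np.mean(np.asarray(vfl) * w))
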