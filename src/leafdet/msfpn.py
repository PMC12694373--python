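"""Multi-scale feature pyramid network (MSFPN) with focusing and diffusion.

The neck consumes three pyramid levels — low ``XL`` (stride 8), middle ``XM``
(stride 16) and high ``XH`` (stride 32) — and produces three detection-scale
outputs.  Its two ingredients:

* **MSF (multi-scale focusing)**: align the three levels at the middle
  resolution (upsample-then-conv the high level, 1x1-conv the middle level,
  adaptively downsample the low level), concatenate to ``F``, run four
  parallel depthwise separable convolutions with kernels {5, 7, 9, 11}, sum
  them to ``D``, and return the residual fusion ``F' = F + Conv1x1(D)``.
* **Context diffusion**: the first MSF output is upsampled to ``XUP`` (joined
  with the low level into ``XRL`` -> RepC3) and stride-2 convolved to ``XC``
  (joined with the high level into ``XRH`` -> RepC3).  A second MSF round over
  (XRL, F1, XRH) yields ``XUP'`` and ``XC'``; the final low output fuses
  ``(XRL, XUP', XUP)`` and the final high output ``(XRH, XC', XC)`` so every
  detection scale sees both rounds of cross-scale context.  The middle output
  is the second MSF's fused map.

Every concatenation asserts exact spatial agreement — misaligned levels fail
loudly with a shape diagnostic rather than being silently cropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, avg_pool2d, concat, upsample_nearest
from .nn.layers import BatchNorm2d, Conv2d, Module, SiLU
from .msdrm import ConvBN, ConvBNAct, _pad_center

__all__ = ["PyramidLevels", "MSF", "RepConvBlock", "RepC3", "MSFPN"]


@dataclass
class PyramidLevels:
    """Backbone features at strides 8 / 16 / 32 (low, middle, high)."""

    low: Tensor
    mid: Tensor
    high: Tensor

    def __post_init__(self):
        self.low = self.low if isinstance(self.low, Tensor) else Tensor(self.low)
        self.mid = self.mid if isinstance(self.mid, Tensor) else Tensor(self.mid)
        self.high = self.high if isinstance(self.high, Tensor) else Tensor(self.high)
        for a, b, name in ((self.low, self.mid, "low/mid"),
                           (self.mid, self.high, "mid/high")):
            if (a.shape[2] != 2 * b.shape[2]) or (a.shape[3] != 2 * b.shape[3]):
                raise ValueError(
                    f"pyramid misaligned at {name}: {a.shape[2:]} vs {b.shape[2:]} "
                    "(each level must be exactly 2x the next)")


def _check_aligned(tensors, context: str):
    sizes = {t.shape[2:] for t in tensors}
    if len(sizes) != 1:
        raise ValueError(
            f"misaligned concatenation in {context}: spatial sizes "
            f"{[t.shape[2:] for t in tensors]}")


class DWSepConv(Module):
    """Depthwise separable convolution: k x k depthwise + 1x1 pointwise."""

    def __init__(self, channels: int, k: int, rng=None):
        super().__init__()
        self.dw = Conv2d(channels, channels, k, groups=channels, bias=False, rng=rng)
        self.pw = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.bn = BatchNorm2d(channels)

    def forward(self, x):
        return self.bn(self.pw(self.dw(x)))


class MSF(Module):
    """Multi-scale focusing block: align, concatenate, multi-kernel fuse.

    Output lives at the middle resolution with ``3 * width`` channels.
    """

    def __init__(self, in_channels: tuple, width: int,
                 kernel_set=(5, 7, 9, 11), rng=None):
        super().__init__()
        c_low, c_mid, c_high = in_channels
        self.from_high = ConvBNAct(c_high, width, 1, rng=rng)   # after upsample
        self.from_mid = ConvBNAct(c_mid, width, 1, rng=rng)
        self.from_low = ConvBNAct(c_low, width, 1, rng=rng)     # after adaptive pool
        self.width = width
        cf = 3 * width
        self.branches = [DWSepConv(cf, k, rng=rng) for k in kernel_set]
        self.out_pw = Conv2d(cf, cf, 1, bias=False, rng=rng)
        self.kernel_set = tuple(kernel_set)

    @property
    def out_channels(self):
        return 3 * self.width

    def forward(self, levels: PyramidLevels) -> Tensor:
        xh = self.from_high(upsample_nearest(levels.high, 2))
        xm = self.from_mid(levels.mid)
        xl = self.from_low(avg_pool2d(levels.low, 2))
        _check_aligned((xh, xm, xl), "MSF focusing")
        f = concat([xh, xm, xl], axis=1)
        d = self.branches[0](f)
        for br in self.branches[1:]:
            d = d + br(f)
        return f + self.out_pw(d)


class RepConvBlock(Module):
    """Residual re-parameterisable block: x + [3x3 conv-BN + 1x1 conv-BN](x).

    With frozen statistics the two branches merge into one 3x3 kernel (the
    identity is a centred delta), so training and merged inference agree.
    """

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.k3 = ConvBN(channels, channels, 3, rng=rng)
        self.k1 = ConvBN(channels, channels, 1, rng=rng)
        self.channels = channels

    def forward(self, x):
        return x + self.k3(x) + self.k1(x)

    def merge(self):
        if self.training:
            raise RuntimeError("merge requires eval mode (frozen statistics)")
        s3, b3 = self.k3.bn.fold()
        s1, b1 = self.k1.bn.fold()
        kernel = self.k3.conv.weight.data * s3[:, None, None, None]
        kernel = kernel + _pad_center(
            self.k1.conv.weight.data * s1[:, None, None, None], 3)
        c = self.channels
        ident = np.zeros((c, c, 3, 3))
        ident[np.arange(c), np.arange(c), 1, 1] = 1.0
        return kernel + ident, b3 + b1

    def forward_merged(self, x):
        from .nn.autograd import conv2d
        kernel, bias = self.merge()
        t = x if isinstance(x, Tensor) else Tensor(x)
        return conv2d(t, Tensor(kernel), Tensor(bias))


class RepC3(Module):
    """Channel-harmonising residual conv block used after each concat.

    A 1x1 projection (identity when widths already agree) followed by a
    re-parameterisable residual 3x3 block.
    """

    def __init__(self, c_in: int, c_out: int, rng=None):
        super().__init__()
        self.proj = None if c_in == c_out else ConvBNAct(c_in, c_out, 1, rng=rng)
        self.block = RepConvBlock(c_out, rng=rng)

    def forward(self, x):
        t = x if isinstance(x, Tensor) else Tensor(x)
        if self.proj is not None:
            t = self.proj(t)
        return self.block(t)


class MSFPN(Module):
    """Two focusing rounds plus context diffusion over a 3-level pyramid.

    ``eq4_literal`` restores the originally printed high-level fusion operand
    (the *low*-level map instead of the high-level one).  That pairing is
    spatially inconsistent — stride 8 against stride 32 — so enabling it
    raises the alignment diagnostic; it exists to make the deviation explicit
    rather than silent.
    """

    def __init__(self, in_channels: tuple, width: int = 256,
                 kernel_set=(5, 7, 9, 11), eq4_literal: bool = False, rng=None):
        super().__init__()
        c_low, c_mid, c_high = in_channels
        self.width = width
        self.eq4_literal = eq4_literal
        self.lat_low = ConvBNAct(c_low, width, 1, rng=rng)
        self.lat_mid = ConvBNAct(c_mid, width, 1, rng=rng)
        self.lat_high = ConvBNAct(c_high, width, 1, rng=rng)

        self.msf1 = MSF((width, width, width), width, kernel_set, rng=rng)
        cf = self.msf1.out_channels
        self.up1_proj = ConvBNAct(cf, width, 1, rng=rng)          # XUP
        self.down1 = ConvBNAct(cf, width, 3, stride=2, rng=rng)   # XC
        self.repc3_low = RepC3(2 * width, width, rng=rng)         # XRL
        self.repc3_high = RepC3(2 * width, width, rng=rng)        # XRH

        self.msf2 = MSF((width, cf, width), width, kernel_set, rng=rng)
        cf2 = self.msf2.out_channels
        self.up2_proj = ConvBNAct(cf2, width, 1, rng=rng)         # XUP'
        self.down2 = ConvBNAct(cf2, width, 3, stride=2, rng=rng)  # XC'

        # residual harmonising convs: when the diffusion weights are zeroed
        # the final low/high outputs reduce exactly to the round-1 RepC3 maps
        self.out_low = ConvBN(3 * width, width, 1, rng=rng)
        self.out_mid = ConvBNAct(cf2, width, 1, rng=rng)
        self.out_high = ConvBN(3 * width, width, 1, rng=rng)

    def forward(self, levels: PyramidLevels):
        xl = self.lat_low(levels.low)
        xm = self.lat_mid(levels.mid)
        xh = self.lat_high(levels.high)

        # round 1: focusing
        f1 = self.msf1(PyramidLevels(xl, xm, xh))
        xup = self.up1_proj(upsample_nearest(f1, 2))
        xc = self.down1(f1)

        _check_aligned((xl, xup), "low-level fusion (XRL)")
        xrl = self.repc3_low(concat([xl, xup], axis=1))
        high_operand = xl if self.eq4_literal else xh
        _check_aligned((high_operand, xc), "high-level fusion (XRH)")
        xrh = self.repc3_high(concat([high_operand, xc], axis=1))

        # round 2: focusing over the fused maps
        f2 = self.msf2(PyramidLevels(xrl, f1, xrh))
        xup2 = self.up2_proj(upsample_nearest(f2, 2))
        xc2 = self.down2(f2)

        # context diffusion: both upsampled maps reach the low scale, both
        # downsampled maps reach the high scale
        _check_aligned((xrl, xup2, xup), "context diffusion (low)")
        out_l = xrl + self.out_low(concat([xrl, xup2, xup], axis=1))
        _check_aligned((xrh, xc2, xc), "context diffusion (high)")
        out_h = xrh + self.out_high(concat([xrh, xc2, xc], axis=1))
        out_m = self.out_mid(f2)
        return out_l, out_m, out_h
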