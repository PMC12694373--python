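"""Multi-scale dilation residual module (MSDRM) and its building blocks.

The module fuses two ideas for extracting multi-scale context from leaf
imagery without inflating inference cost:

* **DWR** (dilation-wise residual): a two-stage residual block — *regional
  residualization* (a plain 3x3 conv-norm-act producing regional features)
  followed by *semantic residualization* (parallel depthwise dilated 3x3
  convolutions at several rates, fused and added back to the input).
* **DRB** (dilated reparam block): one large-kernel convolution in parallel
  with several small dilated convolutions, each with its own normalisation.
  At inference the whole block merges losslessly into a single large kernel:
  a k-kernel with dilation d expands to a sparse ((k-1)d+1)-kernel, and the
  frozen normalisations fold into the weights.

MSDRM keeps DWR's regional stage, retains the first 3x3 (dilation 1) semantic
path for fine local detail, replaces the deeper dilated paths with DRB
sub-modules, and adds a morphological **MaxPool - MinPool** filter on the
regional features so lesion-edge continuity survives the fusion.  All paths
are summed, passed through one shared normalisation, and added to the input
residual; output width always equals input width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.autograd import Tensor, conv2d, max_pool2d
from .nn.layers import BatchNorm2d, Conv2d, Module, SiLU

__all__ = [
    "DRBSpec", "ConvBN", "ConvBNAct", "DRB", "DWR", "MSDRM",
    "maxmin_filter", "MaxMinFilter", "expand_dilated_kernel",
]


# ---------------------------------------------------------------------------
# morphological pre-fusion filter
# ---------------------------------------------------------------------------

def maxmin_filter(x, k: int = 3):
    """Morphological gradient: MaxPool(x) - MinPool(x), stride 1, edge padding.

    MinPool is realised as -MaxPool(-x).  The output is non-negative, zero on
    constant regions, invariant to adding a constant, and highlights edges.
    Accepts a Tensor (differentiable) or a plain NCHW array.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError(f"window size must be odd and >= 3, got {k}")
    as_array = not isinstance(x, Tensor)
    t = Tensor(x) if as_array else x
    hi = max_pool2d(t, k, pad_mode="edge")
    lo = -max_pool2d(-t, k, pad_mode="edge")
    out = hi - lo
    return out.data if as_array else out


class MaxMinFilter(Module):
    def __init__(self, k: int = 3):
        super().__init__()
        if k % 2 == 0 or k < 3:
            raise ValueError(f"window size must be odd and >= 3, got {k}")
        self.k = k

    def forward(self, x):
        return maxmin_filter(x, self.k)


# ---------------------------------------------------------------------------
# conv helpers
# ---------------------------------------------------------------------------

class ConvBN(Module):
    """Convolution (no bias) followed by batch normalisation."""

    def __init__(self, c_in, c_out, k, *, stride=1, dilation=1, groups=1, rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride=stride, dilation=dilation,
                           groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x))


class ConvBNAct(Module):
    def __init__(self, c_in, c_out, k, *, stride=1, dilation=1, groups=1, rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride=stride, dilation=dilation,
                           groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.act = SiLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


# ---------------------------------------------------------------------------
# dilated reparam block
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DRBSpec:
    """Configuration of a dilated reparam block.

    Every small branch's effective receptive field, ``(kernel-1)*dilation+1``,
    must fit inside ``large_kernel`` so the merge is lossless.
    """

    channels: int
    large_kernel: int = 7
    small_branches: tuple = field(default=((3, 1), (3, 2), (3, 3)))
    depthwise: bool = True

    def __post_init__(self):
        if self.large_kernel % 2 == 0:
            raise ValueError("large kernel must be odd")
        for k, d in self.small_branches:
            if k % 2 == 0:
                raise ValueError("branch kernels must be odd")
            eff = (k - 1) * d + 1
            if eff > self.large_kernel:
                raise ValueError(
                    f"branch ({k},{d}) has receptive field {eff} exceeding the "
                    f"large kernel {self.large_kernel}")


def expand_dilated_kernel(w: np.ndarray, dilation: int) -> np.ndarray:
    """Expand a dilated kernel to its dense sparse equivalent.

    Entries are spaced by the dilation rate, e.g. (1-D view) [1,2,3] at
    dilation 2 becomes [1,0,2,0,3].  Works on the trailing two axes.
    """
    if dilation == 1:
        return w.copy()
    *lead, kh, kw = w.shape
    out = np.zeros((*lead, (kh - 1) * dilation + 1, (kw - 1) * dilation + 1),
                   dtype=w.dtype)
    out[..., ::dilation, ::dilation] = w
    return out


def _pad_center(w: np.ndarray, size: int) -> np.ndarray:
    """Zero-pad the trailing two axes symmetrically up to (size, size)."""
    *lead, kh, kw = w.shape
    ph, pw = (size - kh) // 2, (size - kw) // 2
    pad = [(0, 0)] * len(lead) + [(ph, size - kh - ph), (pw, size - kw - pw)]
    return np.pad(w, pad)


class DRB(Module):
    """Parallel large-kernel + dilated small-kernel convolutions.

    The large kernel captures global structure, the small dilated branches
    local detail; branch outputs (each with its own BN) are summed.  After
    freezing the normalisations, :meth:`merge` returns one equivalent
    large-kernel convolution.
    """

    def __init__(self, spec: DRBSpec, rng: np.random.Generator | None = None):
        super().__init__()
        self.spec = spec
        c = spec.channels
        g = c if spec.depthwise else 1
        self.large = ConvBN(c, c, spec.large_kernel, groups=g, rng=rng)
        self.small = [ConvBN(c, c, k, dilation=d, groups=g, rng=rng)
                      for k, d in spec.small_branches]

    def forward(self, x):
        out = self.large(x)
        for branch in self.small:
            out = out + branch(x)
        return out

    def merge(self):
        """Fold all branches into one (kernel, bias) pair; requires eval mode.

        Each branch's BN is folded into its conv weights; dilated kernels are
        expanded to sparse large-kernel equivalents; everything is summed.
        """
        if self.training:
            raise RuntimeError(
                "merge requires frozen normalisation statistics; call eval() first")
        K = self.spec.large_kernel
        scale, shift = self.large.bn.fold()
        kernel = self.large.conv.weight.data * scale[:, None, None, None]
        bias = shift.copy()
        for branch, (k, d) in zip(self.small, self.spec.small_branches):
            s, b = branch.bn.fold()
            w = branch.conv.weight.data * s[:, None, None, None]
            kernel += _pad_center(expand_dilated_kernel(w, d), K)
            bias += b
        return kernel, bias

    def forward_merged(self, x):
        """Single-convolution inference with the merged kernel."""
        kernel, bias = self.merge()
        g = self.spec.channels if self.spec.depthwise else 1
        t = x if isinstance(x, Tensor) else Tensor(x)
        return conv2d(t, Tensor(kernel), Tensor(bias), groups=g)


# ---------------------------------------------------------------------------
# dilation-wise residual block
# ---------------------------------------------------------------------------

class DWR(Module):
    """Two-stage residual block: regional then semantic residualization.

    Stage 1: 3x3 conv-BN-SiLU produces regional features.  Stage 2: one
    depthwise dilated 3x3 conv-BN per dilation rate, summed, reduced by a
    pointwise conv-BN, and added to the input residual.
    """

    def __init__(self, channels: int, dilations=(1, 3, 5),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.regional = ConvBNAct(channels, channels, 3, rng=rng)
        self.paths = [ConvBN(channels, channels, 3, dilation=d,
                             groups=channels, rng=rng) for d in dilations]
        self.fuse = ConvBN(channels, channels, 1, rng=rng)
        self.channels = channels

    def forward(self, x):
        t = x if isinstance(x, Tensor) else Tensor(x)
        if t.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {t.shape[1]}")
        r = self.regional(t)
        s = self.paths[0](r)
        for p in self.paths[1:]:
            s = s + p(r)
        return t + self.fuse(s)


# ---------------------------------------------------------------------------
# the combined module
# ---------------------------------------------------------------------------

class MSDRM(Module):
    """Regional residualization -> {3x3 d=1 path, DRB paths, morphological
    path} -> shared BN -> input residual.  Output width equals input width."""

    def __init__(self, channels: int, *, drb_specs=None, maxmin_k: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.regional = ConvBNAct(channels, channels, 3, rng=rng)
        self.local_path = Conv2d(channels, channels, 3, dilation=1,
                                 bias=False, rng=rng)
        if drb_specs is None:
            drb_specs = (
                DRBSpec(channels, large_kernel=5, small_branches=((3, 1), (3, 2))),
                DRBSpec(channels, large_kernel=7,
                        small_branches=((3, 1), (3, 2), (3, 3))),
            )
        self.drbs = [DRB(s, rng=rng) for s in drb_specs]
        self.morph = MaxMinFilter(maxmin_k)
        self.shared_bn = BatchNorm2d(channels)

    def forward(self, x):
        t = x if isinstance(x, Tensor) else Tensor(x)
        if t.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {t.shape[1]}")
        r = self.regional(t)
        fused = self.local_path(r)
        for drb in self.drbs:
            fused = fused + drb(r)
        fused = fused + self.morph(r)
        return t + self.shared_bn(fused)
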