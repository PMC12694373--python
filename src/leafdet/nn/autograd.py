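"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine supports exactly the operations the detection components need:
broadcasting arithmetic, reductions, element-wise nonlinearities, 2-D
convolution (with stride, dilation and groups), pooling, nearest-neighbour
upsampling, concatenation and a numerically stable binary cross-entropy with
logits.  Gradients are accumulated by a topological backward sweep.

Arrays are kept in float64 so that finite-difference checks and the
reparameterization-equivalence tolerances are meaningful.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "upsample_nearest",
    "bce_with_logits",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected a plain array, got a Tensor")
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(self.data ** p, (self,), backward)

    # -- reductions and shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        s = _sigmoid(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def silu(self):
        s = _sigmoid(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(self.data * s, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


# -- convolution --------------------------------------------------------------

def _conv_windows(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """Strided view of padded input: (N, C, OH, OW, kh, kw)."""
    eff_h = (kh - 1) * dilation + 1
    eff_w = (kw - 1) * dilation + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (eff_h, eff_w), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    return win


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int | None = None, dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight layout (OC, C/groups, kh, kw).

    `padding=None` means "same" padding for stride 1 / odd kernels (the
    symmetric padding every block in the package uses).
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    N, C, H, W = x.data.shape
    OC, Cg, kh, kw = w.data.shape
    if C != Cg * groups or OC % groups:
        raise ValueError(f"channel mismatch: x has {C} channels, weight implies {Cg * groups}")
    if padding is None:
        padding = ((kh - 1) * dilation) // 2
    pad = int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = _conv_windows(xp, kh, kw, stride, dilation)
    OH, OW = win.shape[2], win.shape[3]
    G, OCg = groups, OC // groups
    wing = win.reshape(N, G, Cg, OH, OW, kh, kw)
    wg = w.data.reshape(G, OCg, Cg, kh, kw)
    out = np.einsum("ngcxyhw,gkchw->ngkxy", wing, wg, optimize=True)
    out = out.reshape(N, OC, OH, OW)
    if b is not None:
        out = out + b.data.reshape(1, OC, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gg = g.reshape(N, G, OCg, OH, OW)
        if w.requires_grad:
            gw = np.einsum("ngcxyhw,ngkxy->gkchw", wing, gg, optimize=True)
            w._accum(gw.reshape(OC, Cg, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("gkchw,ngkxy->ngcxyhw", wg, gg, optimize=True)
            gcols = gcols.reshape(N, C, OH, OW, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                ii = i * dilation
                for j in range(kw):
                    jj = j * dilation
                    gxp[:, :, ii:ii + OH * stride:stride,
                        jj:jj + OW * stride:stride] += gcols[:, :, :, :, i, j]
            if pad:
                x._accum(gxp[:, :, pad:pad + H, pad:pad + W])
            else:
                x._accum(gxp)

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, k: int, *, stride: int = 1, pad_mode: str = "edge") -> Tensor:
    """Sliding-window max with symmetric padding (default replicate edges)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    if k % 2 == 0 or k < 1:
        raise ValueError("pooling window must be odd")
    N, C, H, W = x.data.shape
    pad = (k - 1) // 2
    if pad_mode == "edge":
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="edge")
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                    constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    OH, OW = win.shape[2], win.shape[3]
    flat = win.reshape(N, C, OH, OW, k * k)
    am = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dh, dw = np.divmod(am, k)
        oi = np.arange(OH)[None, None, :, None] * stride
        oj = np.arange(OW)[None, None, None, :] * stride
        # replicate padding folds border gradients back onto edge pixels
        ri = np.clip(oi + dh - pad, 0, H - 1)
        rj = np.clip(oj + dw - pad, 0, W - 1)
        gx = np.zeros_like(x.data)
        n_idx = np.arange(N)[:, None, None, None]
        c_idx = np.arange(C)[None, :, None, None]
        np.add.at(gx, (np.broadcast_to(n_idx, am.shape), np.broadcast_to(c_idx, am.shape),
                       ri, rj), g)
        x._accum(gx)

    return Tensor._make(out, (x,), backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling (spatial size must divide by k)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"spatial size ({H},{W}) not divisible by pool factor {k}")
    r = x.data.reshape(N, C, H // k, k, W // k, k)
    out = r.mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accum(gx)

    return Tensor._make(out, (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    N, C, H, W = x.data.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def backward(g):
        if x.requires_grad:
            gx = g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
            x._accum(gx)

    return Tensor._make(out, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Element-wise binary cross-entropy in logit space.

    Uses the max(x,0) - x*t + log1p(exp(-|x|)) form, stable for any logit.
    Targets are treated as constants (the IoU-aware targets carry no gradient).
    """
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    t = _as_array(targets)
    x = logits.data
    out = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        if logits.requires_grad:
            logits._accum(g * (_sigmoid(x) - t))

    return Tensor._make(out, (logits,), backward)
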