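"""Neural-network layers built on the autograd engine.

Conventions follow the usual detection-framework layout: NCHW feature maps,
He-initialised convolutions, batch normalisation with running statistics, and
SiLU activations.  Modules expose ``parameters()`` / ``named_parameters()``,
``train()`` / ``eval()``, and can be zeroed wholesale for the residual-identity
tests the block contracts require.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = [
    "Module", "Parameter", "Conv2d", "BatchNorm2d", "SiLU", "Identity",
    "Sequential", "SGD", "count_parameters", "zero_parameters",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container; submodules and parameters are attributes."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def count_parameters(module: Module) -> int:
    return sum(p.data.size for p in module.parameters())


def zero_parameters(module: Module) -> Module:
    """Set every learnable parameter (incl. norm scales/offsets) to zero."""
    for p in module.parameters():
        p.data[...] = 0.0
    return module


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *,
                 stride: int = 1, padding: int | None = None, dilation: int = 1,
                 groups: int = 1, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide groups")
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale,
                                size=(out_channels, in_channels // groups,
                                      kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, *, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps = eps
        self.momentum = momentum
        self.num_features = num_features

    def forward(self, x: Tensor) -> Tensor:
        sh = (1, self.num_features, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.reshape(sh))
            var = Tensor(self.running_var.reshape(sh))
            xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(sh) + self.beta.reshape(sh)

    def fold(self):
        """Return (scale, shift) per channel for folding into a conv (eval stats)."""
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data * inv
        shift = self.beta.data - self.gamma.data * self.running_mean * inv
        return scale, shift


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
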