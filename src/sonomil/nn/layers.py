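"""Trainable layers built on the autodiff core.

Modules register their parameters and submodules by attribute assignment,
expose ``parameters()`` / ``state_dict()`` in the usual way, and carry a
``training`` flag toggled by ``train()`` / ``eval()``.  All parameters are
float32 by default; layers take an explicit ``rng`` so initialisation is
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "Linear",
    "GroupNorm",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = name
        object.__setattr__(self, name, np.asarray(value))

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: np.asarray(b).copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(d)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(d[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        # buffers live on nested modules; walk again to assign them in place
        self._assign_buffers(d, prefix="")

    def _assign_buffers(self, d, prefix=""):
        for name in self._buffers:
            object.__setattr__(self, name, np.asarray(d[prefix + name]).copy())
        for name, m in self._modules.items():
            m._assign_buffers(d, prefix + name + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """He-initialised 2-D convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_dim)
        self.weight = Parameter(rng.normal(0.0, std, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1)
        return out


class GroupNorm(Module):
    """Group normalisation over [N,C,H,W]; deterministic in both modes."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.groups = groups
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x):
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        xn = xn.reshape(n, c, h, w)
        return xn * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class BatchNorm2d(Module):
    """Batch normalisation with running statistics for evaluation mode."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xn = xc * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
            xn = (x - mu) * (var + self.eps) ** -0.5
        return xn * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Dropout(Module):
    """Inverted dropout drawing from its own seeded generator stream."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        return F.dropout(x, self.p, self.rng, self.training)
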