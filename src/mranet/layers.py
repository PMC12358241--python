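"""Neural-network layer library on top of the autodiff engine.

Provides the module/parameter system (named parameter traversal, train/eval
modes, state dicts) plus the concrete layers the segmentation network is
assembled from: Conv2d, BatchNorm2d, LayerNorm, Linear, and the Adam optimiser.
Weight initialisation follows the Kaiming fan-in convention for convolutions
and truncated-free normal(0, 0.02) for transformer projections.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Identity",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "Linear",
    "Adam",
    "set_seed",
    "get_rng",
]

# Global generator used by all weight initialisers. Reset with set_seed()
# before building a model to make construction reproducible.
_RNG = np.random.default_rng(0)


def set_seed(seed: int) -> None:
    """Seed weight initialisation (and only that) globally."""
    global _RNG
    _RNG = np.random.default_rng(int(seed))


def get_rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    """A trainable tensor; ``requires_grad`` may be cleared to freeze it."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=ad.DTYPE), requires_grad=True)


class Module:
    """Base class: children and parameters are discovered via attributes."""

    def __init__(self):
        self._parameters: "OrderedDict[str, Parameter]" = OrderedDict()
        self._buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=ad.DTYPE)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=ad.DTYPE)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True) -> "Module":
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialisation -----------------------------------------------------
    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        out: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, b in self.named_buffers():
            out["buffer:" + name] = b.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        expected = set(params)
        expected_buf = {name for name, _ in self.named_buffers()}
        for key, value in state.items():
            value = np.asarray(value, dtype=ad.DTYPE)
            if key.startswith("buffer:"):
                name = key[len("buffer:"):]
                if name not in expected_buf:
                    raise KeyError(f"unexpected buffer in checkpoint: {name!r}")
                self._assign_buffer(name, value)
            else:
                if key not in params:
                    raise KeyError(f"unexpected parameter in checkpoint: {key!r}")
                if params[key].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for parameter {key!r}: model has "
                        f"{params[key].data.shape}, checkpoint has {value.shape}")
                params[key].data = value.copy()
        missing = expected - {k for k in state if not k.startswith("buffer:")}
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:3]} ...")

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        mod: Module = self
        for part in parts[:-1]:
            mod = mod._modules[part]
        name = parts[-1]
        if value.shape != mod._buffers[name].shape:
            raise ValueError(f"shape mismatch for buffer {dotted!r}")
        mod._set_buffer(name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for mod in mods:
            self.append(mod)

    def append(self, mod: Module) -> None:
        self._modules[str(len(self._list))] = mod
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._list = list(mods)
        for i, mod in enumerate(mods):
            self._modules[str(i)] = mod

    def forward(self, x):
        for mod in self._list:
            x = mod(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(_RNG.normal(
            0.0, std, size=(out_channels, in_channels // groups,
                            kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation,
                         groups=self.groups)


class BatchNorm2d(Module):
    """Batch statistics in train mode, running estimates in eval mode."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_features
        if x.shape[1] != c:
            raise ValueError(f"BatchNorm2d expected {c} channels, got {x.shape[1]}")
        shape = (1, c, 1, 1)
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbias = n / max(n - 1, 1)
            rm = (1 - self.momentum) * self.running_mean \
                + self.momentum * mean.data.reshape(c)
            rv = (1 - self.momentum) * self.running_var \
                + self.momentum * var.data.reshape(c) * unbias
            self._set_buffer("running_mean", rm)
            self._set_buffer("running_var", rv)
            xhat = centred * ad.power(var + self.eps, -0.5)
        else:
            mean = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mean) * ad.power(var + self.eps, -0.5)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class LayerNorm(Module):
    """Normalisation over the last dimension (transformer token features)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centred = x - mean
        var = (centred * centred).mean(axis=-1, keepdims=True)
        xhat = centred * ad.power(var + self.eps, -0.5)
        return xhat * self.weight + self.bias


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 std: float = 0.02):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_RNG.normal(0.0, std, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class Adam:
    """Adam optimiser (Kingma & Ba) over a parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
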