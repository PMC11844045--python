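"""Minimal neural-network layer library over :mod:`vesselseg.autodiff`.

Provides the ``Module`` container protocol (parameter traversal,
train/eval modes, state dicts) and the concrete layers the segmentation
network is built from.  Initialization is fully reproducible: every
module draws its weights from a ``numpy.random.Generator`` passed in at
construction, using a truncated-normal fan-in scheme.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "BatchNorm2d", "ConvBNReLU", "Identity"]


class Parameter(Tensor):
    """A trainable tensor (always requires gradient)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal(0, std) samples re-drawn (by clipping) to +/- 2 std."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2.0 * std, 2.0 * std).astype(np.float32)


class Module:
    """Base class: children auto-registered through attribute assignment."""

    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def add_module(self, name: str, module: "Module") -> None:
        self._modules[name] = module
        object.__setattr__(self, name, module)

    # -- traversal ------------------------------------------------------------
    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state ----------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer::" + name] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer::"):
                buf = buffers[key[len("buffer::"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {p.data.shape} vs {value.shape}")
                p.data = value.astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ModuleList(Module):
    """Ordered container registering its items as child modules."""

    def __init__(self, items=()):
        super().__init__()
        self._items: list[Module] = []
        for item in items:
            self.append(item)

    def append(self, module: Module) -> None:
        self.add_module(str(len(self._items)), module)
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


class Conv2d(Module):
    """Stride-1 same-padded convolution with optional dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1, bias: bool = True):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(
            trunc_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), std))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, training=self.training,
                             momentum=self.momentum, eps=self.eps)


class ConvBNReLU(Module):
    """The Conv2d + BN + ReLU unit every encoder/decoder level is made of.

    Same-padding at stride 1 (padding = dilation) so the spatial size is
    always preserved; all activations are non-negative.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, dilation: int = 1):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, rng, dilation=dilation)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.conv.in_channels:
            raise ValueError(
                f"channel mismatch: got {x.shape[1]}, expected {self.conv.in_channels}")
        return ad.relu(self.bn(self.conv(x)))
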