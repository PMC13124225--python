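"""Torch-like module containers built on the numpy autograd core."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import core
from .core import Tensor

_GLOBAL_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the generator used for parameter init, dropout and drop-path."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _GLOBAL_RNG


def trunc_normal(shape, std: float = 0.02) -> np.ndarray:
    x = _GLOBAL_RNG.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).items():
            pass
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state ----------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.shape}")
            p.data = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x, *args):
        return x


class ModuleList(Module):
    def __init__(self, items=()):
        super().__init__()
        self.items = list(items)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal((in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        y = core.matmul(x, self.weight)
        if self.bias is not None:
            y = core.add(y, self.bias)
        return y


class Conv2d(Module):
    """Same-padded NHWC convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, bias: bool = True):
        super().__init__()
        self.stride = stride
        fan_in = kernel * kernel * in_channels
        self.weight = Parameter(
            trunc_normal((kernel, kernel, in_channels, out_channels), std=float(fan_in) ** -0.5)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return core.conv2d(x, self.weight, self.bias, stride=self.stride)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, bias: bool = True):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"depthwise kernel must be odd, got {kernel}")
        self.weight = Parameter(trunc_normal((kernel, kernel, channels), std=float(kernel * kernel) ** -0.5))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x):
        return core.depthwise_conv2d(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x):
        return core.layer_norm(x, self.weight, self.bias, self.eps)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x):
        return core.dropout(x, self.p, _GLOBAL_RNG, self.training)


class DropPath(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x):
        return core.drop_path(x, self.p, _GLOBAL_RNG, self.training)


class Mlp(Module):
    """Two-layer feedforward with GELU, applied along the channel axis."""

    def __init__(self, dim: int, hidden: int):
        super().__init__()
        self.fc1 = Linear(dim, hidden)
        self.fc2 = Linear(hidden, dim)

    def forward(self, x):
        return self.fc2(core.gelu(self.fc1(x)))
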