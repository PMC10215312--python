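"""Layer/module system built on the autograd tensor.

Mirrors the familiar torch.nn surface (Module, Conv2d, BatchNorm2d, Linear,
Sequential, ...) at the scale this project needs.  Parameters are Tensors with
``requires_grad=True``; buffers (batch-norm running statistics) are plain
arrays carried in ``state_dict`` but never updated by the optimizer.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, maxpool2d

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Identity",
    "set_seed",
]

_rng = np.random.default_rng(0)


def set_seed(seed: int) -> None:
    """Reseed the generator used for parameter initialization."""
    global _rng
    _rng = np.random.default_rng(seed)


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)
        object.__setattr__(self, "_record_output", False)
        object.__setattr__(self, "_last_output", None)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -------------------------------------------------------------- traversal
    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix.rstrip("."), self
        for name, m in self._modules.items():
            yield from m.named_modules(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        for _, m in self.named_modules():
            yield m

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # ------------------------------------------------------------ persistence
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name, b in self._buffers.items():
            out[prefix + name] = b
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = np.asarray(state[prefix + name], dtype=np.float32)
        for name in self._buffers:
            self._buffers[name] = np.asarray(
                state[prefix + name], dtype=np.float32
            )
            object.__setattr__(self, name, self._buffers[name])
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    # --------------------------------------------------------------- dispatch
    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs) -> Tensor:
        out = self.forward(*args, **kwargs)
        if self._record_output:
            object.__setattr__(self, "_last_output", out)
        return out


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._modules.values())

    def forward(self, x: Tensor) -> Tensor:
        for m in self._modules.values():
            x = m(x)
        return x


class Conv2d(Module):
    """Grouped 2-d convolution; He fan-out init, bias off by default."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride=1,
        padding=0,
        groups: int = 1,
        bias: bool = False,
    ):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        kh, kw = (
            (kernel_size, kernel_size)
            if isinstance(kernel_size, int)
            else kernel_size
        )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = (kh, kw)
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_out = kh * kw * out_channels // groups
        std = math.sqrt(2.0 / fan_out)
        self.weight = Parameter(
            _rng.normal(0.0, std, (out_channels, in_channels // groups, kh, kw))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            groups=self.groups,
        )


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers["running_mean"] = self.running_mean
        self._buffers["running_var"] = self.running_var

    def forward(self, x: Tensor) -> Tensor:
        gamma = self.weight.reshape(1, self.channels, 1, 1)
        beta = self.bias.reshape(1, self.channels, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu.data.ravel()
            n = x.size / self.channels
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var *= 1 - m
            self.running_var += m * unbiased
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(1, self.channels, 1, 1))
            inv = Tensor(
                1.0
                / np.sqrt(self.running_var.reshape(1, self.channels, 1, 1) + self.eps)
            )
            xhat = (x - mu) * inv
        return gamma * xhat + beta


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(
            _rng.uniform(-bound, bound, (out_features, in_features))
        )
        self.bias = Parameter(_rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel_size, self.stride, self.padding)


class GlobalAvgPool2d(Module):
    def __init__(self, keepdims: bool = True):
        super().__init__()
        self.keepdims = keepdims

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3), keepdims=self.keepdims)
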