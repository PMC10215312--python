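"""Depthwise separable convolution: building block and closed-form accounting.

The accounting treats a bias-free K×K convolution over an S×S×C input
producing N output channels.  A standard convolution spends K·K·C·N weights
and S·S·K·K·C·N multiply–accumulates; the separable factorization spends
K·K·C + C·N weights and S·S·(K·K·C + C·N) operations, a reduction factor of
1/N + 1/K² for both.  The instantiable layer and the squeeze-and-excitation
gate used by the down-sampling module live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import nn
from .nn import Tensor

__all__ = [
    "ConvSpec",
    "ParamCount",
    "count_standard",
    "count_dsc",
    "flops_standard",
    "flops_dsc",
    "ratios",
    "accounting",
    "build_dsc_layer",
    "build_se_unit",
    "DepthwiseSeparableConv",
    "SqueezeExcite",
]


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class ConvSpec:
    """Shape description of one square convolution, for accounting.

    ``spatial_size`` is the input height (= width); ``include_bias`` must stay
    False for the closed forms to match instantiated weight counts.
    """

    in_channels: int
    out_channels: int
    kernel: int
    stride: int = 1
    spatial_size: int = 1
    include_bias: bool = False

    def __post_init__(self):
        for name in ("in_channels", "out_channels", "kernel", "stride", "spatial_size"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise InvalidSpecError(f"{name} must be a positive integer, got {v!r}")
        if self.include_bias:
            raise InvalidSpecError("accounting is defined for bias-free convolutions")


@dataclass(frozen=True)
class ParamCount:
    standard_params: int
    dsc_params: int
    standard_flops: int
    dsc_flops: int
    param_ratio: float
    flop_ratio: float


def count_standard(spec: ConvSpec) -> int:
    """Weights of a standard convolution: K·K·C·N."""
    return spec.kernel * spec.kernel * spec.in_channels * spec.out_channels


def count_dsc(spec: ConvSpec) -> int:
    """Weights of the depthwise+pointwise pair: K·K·C + C·N."""
    c, n, k = spec.in_channels, spec.out_channels, spec.kernel
    return k * k * c + c * n


def flops_standard(spec: ConvSpec) -> int:
    """Multiply–accumulates of the standard convolution: S·S·K·K·C·N.

    Evaluated as printed with S the input size; stride is deliberately not
    folded in.
    """
    s = spec.spatial_size
    return s * s * count_standard(spec)


def flops_dsc(spec: ConvSpec) -> int:
    """Multiply–accumulates of the separable pair: S·S·K·K·C + S·S·C·N."""
    s, c, n, k = spec.spatial_size, spec.in_channels, spec.out_channels, spec.kernel
    return s * s * k * k * c + s * s * c * n


def ratios(spec: ConvSpec) -> tuple[float, float]:
    """(param ratio, flop ratio); both equal 1/N + 1/K² in closed form."""
    closed = 1.0 / spec.out_channels + 1.0 / spec.kernel**2
    fw = count_dsc(spec) / count_standard(spec)
    fo = flops_dsc(spec) / flops_standard(spec)
    if abs(fw - closed) > 1e-12 or abs(fo - closed) > 1e-12:
        raise AssertionError("closed form and explicit quotient disagree")
    return fw, fo


def accounting(spec: ConvSpec) -> ParamCount:
    fw, fo = ratios(spec)
    return ParamCount(
        standard_params=count_standard(spec),
        dsc_params=count_dsc(spec),
        standard_flops=flops_standard(spec),
        dsc_flops=flops_dsc(spec),
        param_ratio=fw,
        flop_ratio=fo,
    )


class DepthwiseSeparableConv(nn.Module):
    """Per-channel K×K convolution followed by 1×1 channel mixing.

    Same padding (K//2); with stride 2 an even input is exactly halved.
    ``norm`` selects batch-norm/ReLU placement: "none" (bare, weight count
    equals the Eq-17 figure), "post" (after the pointwise stage only) or
    "both".  ``pointwise_groups`` lets the channel mixing stay within groups,
    which is what makes a grouped DSC equivalent to independent per-split
    DSCs in the split-attention block.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        norm: str = "none",
        pointwise_groups: int = 1,
    ):
        super().__init__()
        if stride < 1:
            raise InvalidSpecError("stride must be >= 1")
        if norm not in ("none", "post", "both"):
            raise InvalidSpecError(f"unknown norm placement {norm!r}")
        self.depthwise = nn.Conv2d(
            in_channels,
            in_channels,
            kernel,
            stride=stride,
            padding=kernel // 2,
            groups=in_channels,
        )
        self.pointwise = nn.Conv2d(
            in_channels, out_channels, 1, groups=pointwise_groups
        )
        self.norm = norm
        if norm == "both":
            self.bn_depth = nn.BatchNorm2d(in_channels)
        if norm in ("post", "both"):
            self.bn_point = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        y = self.depthwise(x)
        if self.norm == "both":
            y = self.bn_depth(y).relu()
        y = self.pointwise(y)
        if self.norm in ("post", "both"):
            y = self.bn_point(y).relu()
        return y


def build_dsc_layer(spec: ConvSpec, norm: str = "none") -> DepthwiseSeparableConv:
    """Instantiate the separable layer described by ``spec``.

    With ``norm="none"`` the trainable weight count equals ``count_dsc(spec)``.
    """
    return DepthwiseSeparableConv(
        spec.in_channels, spec.out_channels, spec.kernel, spec.stride, norm=norm
    )


class SqueezeExcite(nn.Module):
    """Channel gate: global average pool → bottleneck → expand → sigmoid."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels < 1:
            raise InvalidSpecError("channels must be >= 1")
        if reduction < 1:
            raise InvalidSpecError("reduction must be >= 1")
        hidden = max(1, math.ceil(channels / reduction))
        self.pool = nn.GlobalAvgPool2d()
        self.fc1 = nn.Conv2d(channels, hidden, 1, bias=True)
        self.fc2 = nn.Conv2d(hidden, channels, 1, bias=True)
        self.hidden = hidden
        self.channels = channels

    def gate(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(self.pool(x)).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


def build_se_unit(channels: int, reduction: int = 16) -> SqueezeExcite:
    return SqueezeExcite(channels, reduction)
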