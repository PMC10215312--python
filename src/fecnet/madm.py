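"""Multi-scale attention down-sampling.

Three stride-2 branches — 3×3 max pooling, a 5×5 separable convolution and a
7×7 separable convolution — are concatenated on the channel axis, projected
to the output width by a bias-free 1×1 convolution, and gated by a
squeeze-and-excitation unit.  Replaces plain pooled down-sampling so small
features survive the resolution drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import nn
from .conv_primitives import DepthwiseSeparableConv, SqueezeExcite
from .nn import Tensor, as_tensor, concat

__all__ = ["MadmConfig", "MADM", "madm_forward", "madm_param_count", "MadmParams"]


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MadmConfig:
    in_channels: int
    out_channels: int
    se_reduction: int = 16
    # fixed by construction: branch kernels (pool, 5, 7), stride 2

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise InvalidConfigError("channel counts must be positive")
        if self.se_reduction < 1:
            raise InvalidConfigError("se_reduction must be positive")


class MADM(nn.Module):
    def __init__(self, cfg: MadmConfig):
        super().__init__()
        self.cfg = cfg
        c_in, c_out = cfg.in_channels, cfg.out_channels
        self.pool = nn.MaxPool2d(3, stride=2, padding=1)
        self.dsc5 = DepthwiseSeparableConv(c_in, c_out, kernel=5, stride=2, norm="post")
        self.dsc7 = DepthwiseSeparableConv(c_in, c_out, kernel=7, stride=2, norm="post")
        self.project = nn.Conv2d(c_in + 2 * c_out, c_out, 1)
        self.bn = nn.BatchNorm2d(c_out)
        self.se = SqueezeExcite(c_out, cfg.se_reduction)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if x.ndim != 4:
            raise InvalidConfigError("expected NCHW input")
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise InvalidConfigError("spatial size must be >= 2 to down-sample")
        branches = [self.pool(x), self.dsc5(x), self.dsc7(x)]
        fused = self.bn(self.project(concat(branches, axis=1))).relu()
        return self.se(fused)


def madm_forward(x, cfg: MadmConfig) -> Tensor:
    return MADM(cfg)(x)


@dataclass(frozen=True)
class MadmParams:
    conv_params: int  # closed-form conv-weight terms only
    norm_params: int  # batch-norm affine pairs
    se_params: int  # gate weights + biases
    total: int


def madm_param_count(cfg: MadmConfig) -> MadmParams:
    """Closed-form trainable-scalar count of an instantiated module.

    ``conv_params`` is the sum of the separable-convolution counts
    (K²·C + C·N for K = 5, 7) plus the 1×1 projection ((C+2N)·N); the max-pool
    branch contributes nothing.  ``total`` adds batch-norm affine pairs and
    the squeeze-excitation weights so it matches weight enumeration exactly.
    """
    c, n = cfg.in_channels, cfg.out_channels
    dsc5 = 25 * c + c * n
    dsc7 = 49 * c + c * n
    proj = (c + 2 * n) * n
    conv = dsc5 + dsc7 + proj
    norm = 2 * n * 3  # bn after each dsc pointwise stage + after projection
    hidden = max(1, math.ceil(n / cfg.se_reduction))
    se = n * hidden + hidden + hidden * n + n
    return MadmParams(conv_params=conv, norm_params=norm, se_params=se, total=conv + norm + se)
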