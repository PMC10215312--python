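"""Coordinate location attention.

Three copies of the input feed three branches: directional average pooling
along height and along width produces two one-dimensional positional
encodings, each refined by a location-attention unit (LAM: smoothing pool,
then the elementwise product of a per-position fully-connected path and a
3×3 separable-convolution path); the third branch is the input itself with
the global per-channel descriptor broadcast-added.  The branch product is
normalized (softmax over channels, rescaled by C, or a sigmoid gate) and
applied multiplicatively to the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .conv_primitives import DepthwiseSeparableConv
from .nn import Tensor, as_tensor, concat

__all__ = [
    "LamConfig",
    "LAM",
    "CLAM",
    "CoordinateAttention",
    "coordinate_embed",
    "directional_pool_h",
    "directional_pool_w",
    "transpose_h_encoding",
]


class InvalidInputError(ValueError):
    pass


def _as_4d(x) -> Tensor:
    x = as_tensor(x)
    if x.ndim == 3:  # C,H,W -> 1,C,H,W
        x = x.reshape(1, *x.shape)
    if x.ndim != 4:
        raise InvalidInputError(f"expected a 3-d or 4-d feature map, got ndim={x.ndim}")
    if x.shape[2] < 1 or x.shape[3] < 1:
        raise InvalidInputError("empty spatial extent")
    return x


def coordinate_embed(x) -> Tensor:
    """Global spatial mean per channel: Z[c] = (1/hw)·Σᵢⱼ x[c,i,j]."""
    return _as_4d(x).mean(axis=(2, 3), keepdims=True)


def directional_pool_h(x) -> Tensor:
    """Row means along width → encoding of shape (B, C, h, 1)."""
    return _as_4d(x).mean(axis=3, keepdims=True)


def directional_pool_w(x) -> Tensor:
    """Column means along height → encoding of shape (B, C, 1, w)."""
    return _as_4d(x).mean(axis=2, keepdims=True)


def transpose_h_encoding(z_h: Tensor) -> Tensor:
    """Swap the two spatial axes of a (B, C, h, 1) encoding → (B, C, 1, h)."""
    z_h = as_tensor(z_h)
    if z_h.ndim != 4:
        raise InvalidInputError("directional encodings are 4-d (B, C, L, 1)")
    return z_h.transpose(0, 1, 3, 2)


def _smooth_pool(f: Tensor) -> Tensor:
    """Average pool, window 2, stride 1, same length (replicate right edge)."""
    L = f.shape[3]
    if L == 1:
        return f
    shifted = concat([f.narrow(3, 1, L - 1), f.narrow(3, L - 1, 1)], axis=3)
    return (f + shifted) * 0.5


@dataclass(frozen=True)
class LamConfig:
    channels: int
    fc_hidden: int | None = None  # None: channel-to-channel, no reduction
    dsc_kernel: int = 3
    pool: str = "smooth"  # "smooth" (window-2 stride-1) or "none" (identity)

    def __post_init__(self):
        if self.channels < 1:
            raise InvalidInputError("channels must be positive")
        if self.dsc_kernel != 3:
            raise InvalidInputError("the separable kernel is fixed at 3")
        if self.pool not in ("smooth", "none"):
            raise InvalidInputError(f"unknown pool {self.pool!r}")


class LAM(nn.Module):
    """Location attention unit over a 1-d directional encoding (B, C, 1, L)."""

    def __init__(self, cfg: LamConfig):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        if cfg.fc_hidden is None:
            self.fc = nn.Conv2d(c, c, 1, bias=True)
        else:
            self.fc = nn.Sequential(
                nn.Conv2d(c, cfg.fc_hidden, 1, bias=True),
                nn.ReLU(),
                nn.Conv2d(cfg.fc_hidden, c, 1, bias=True),
            )
        self.dsc = DepthwiseSeparableConv(c, c, kernel=cfg.dsc_kernel)

    def forward(self, f: Tensor) -> Tensor:
        f = as_tensor(f)
        if f.ndim != 4 or f.shape[2] != 1:
            raise InvalidInputError("LAM expects a (B, C, 1, L) encoding")
        if f.shape[1] != self.cfg.channels:
            raise InvalidInputError(
                f"channel mismatch: config {self.cfg.channels}, input {f.shape[1]}"
            )
        pooled = _smooth_pool(f) if self.cfg.pool == "smooth" else f
        return self.fc(pooled) * self.dsc(pooled)


class CLAM(nn.Module):
    """Coordinate location attention applied multiplicatively to the input.

    ``gate`` chooses the normalization of the fused branch product:
    ``"softmax"`` (over channels at each location, rescaled by C so the mean
    gate is ~1) or ``"sigmoid"``.
    """

    def __init__(self, channels: int, gate: str = "softmax"):
        super().__init__()
        if gate not in ("softmax", "sigmoid"):
            raise InvalidInputError(f"unknown gate {gate!r}")
        self.channels = channels
        self.gate = gate
        cfg = LamConfig(channels)
        self.lam_h = LAM(cfg)
        self.lam_w = LAM(cfg)

    def attention(self, x) -> Tensor:
        """The multiplicative attention map, same shape as the input."""
        x = _as_4d(x)
        if x.shape[1] != self.channels:
            raise InvalidInputError(
                f"channel mismatch: module {self.channels}, input {x.shape[1]}"
            )
        a_h = transpose_h_encoding(
            self.lam_h(transpose_h_encoding(directional_pool_h(x)))
        )  # varies along height: (B, C, h, 1)
        a_w = self.lam_w(directional_pool_w(x))  # varies along width: (B, C, 1, w)
        a_c = x + coordinate_embed(x)  # third branch
        score = a_h * a_w * a_c
        if self.gate == "softmax":
            return score.softmax(axis=1) * float(self.channels)
        return score.sigmoid()

    def forward(self, x) -> Tensor:
        x = _as_4d(x)
        return x * self.attention(x)


class CoordinateAttention(nn.Module):
    """Plain coordinate attention (comparison variant for the ablation grid).

    Directional pooled encodings are concatenated, mixed by a shared 1×1
    conv, split back, and turned into sigmoid gates along each axis.
    """

    def __init__(self, channels: int, reduction: int = 8):
        super().__init__()
        hidden = max(4, channels // reduction)
        self.channels = channels
        self.mix = nn.Sequential(
            nn.Conv2d(channels, hidden, 1),
            nn.BatchNorm2d(hidden),
            nn.ReLU(),
        )
        self.attn_h = nn.Conv2d(hidden, channels, 1, bias=True)
        self.attn_w = nn.Conv2d(hidden, channels, 1, bias=True)

    def forward(self, x) -> Tensor:
        x = _as_4d(x)
        h, w = x.shape[2], x.shape[3]
        zh = transpose_h_encoding(directional_pool_h(x))  # (B, C, 1, h)
        zw = directional_pool_w(x)  # (B, C, 1, w)
        mixed = self.mix(concat([zh, zw], axis=3))
        gh = transpose_h_encoding(self.attn_h(mixed.narrow(3, 0, h))).sigmoid()
        gw = self.attn_w(mixed.narrow(3, h, w)).sigmoid()
        return x * gh * gw
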