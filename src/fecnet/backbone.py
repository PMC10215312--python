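"""Split-attention residual blocks and four-stage classification networks.

The block bottleneck is split into cardinal × radix channel groups; within
each cardinal group the radix splits are summed, globally pooled, and
re-weighted by a soft assignment (softmax over radix when radix > 1, a
sigmoid gate when radix = 1) before the weighted sum is concatenated across
cardinal groups.  Blocks optionally prepend a coordinate-attention unit,
swap the 3×3 convolution for its depthwise-separable equivalent, and
down-sample either conventionally (strided conv / pooled stem) or through
the multi-scale attention down-sampling module.

Width convention: the per-block group width is ``base_bottleneck × cardinal``
(the ResNeXt/ResNeSt convention), so parameter counts grow monotonically in
both radix and cardinal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .clam import CLAM, CoordinateAttention
from .conv_primitives import DepthwiseSeparableConv
from .madm import MADM, MadmConfig
from .nn import Tensor, as_tensor, concat

__all__ = [
    "BlockConfig",
    "NetworkConfig",
    "SplitAttention",
    "split_attention",
    "SCMBlock",
    "scm_block_forward",
    "ResBottleneck",
    "Network",
    "build_network",
    "count_parameters",
    "scheme_config",
    "preset_config",
    "SCHEMES",
    "PRESETS",
]


class InvalidConfigError(ValueError):
    pass


# --------------------------------------------------------------- split attention
class SplitAttention(nn.Module):
    """Soft weighting over radix feature splits, per cardinal group.

    ``channels`` is the width of one split.  Each cardinal group owns a
    two-layer gate network c → max(c//4, 4) → r·c with BN+ReLU between.
    """

    def __init__(self, channels: int, radix: int, cardinal: int):
        super().__init__()
        if channels < 1 or radix < 1 or cardinal < 1:
            raise InvalidConfigError("channels, radix, cardinal must be positive")
        self.channels = channels
        self.radix = radix
        self.cardinal = cardinal
        hidden = max(channels // 4, 4)
        self.gates = nn.ModuleList(
            nn.Sequential(
                nn.Conv2d(channels, hidden, 1, bias=True),
                nn.BatchNorm2d(hidden),
                nn.ReLU(),
                nn.Conv2d(hidden, radix * channels, 1, bias=True),
            )
            for _ in range(cardinal)
        )
        # zero-init the scoring layer: identical splits start at exactly
        # uniform weights (1/r), the gate learns its preference from there
        for gate in self.gates:
            last = gate._modules["3"]
            last.weight.data[:] = 0.0
            last.bias.data[:] = 0.0
        self.last_weights: np.ndarray | None = None

    def forward(self, splits: list[Tensor]) -> Tensor:
        r, k, c = self.radix, self.cardinal, self.channels
        if len(splits) != k * r:
            raise InvalidConfigError(
                f"expected {k * r} splits (cardinal*radix), got {len(splits)}"
            )
        splits = [as_tensor(s) for s in splits]
        shape = splits[0].shape
        for s in splits:
            if s.shape != shape:
                raise InvalidConfigError("all splits must share one shape")
        if shape[1] != c:
            raise InvalidConfigError(
                f"split width {shape[1]} does not match module width {c}"
            )
        outs: list[Tensor] = []
        weights: list[np.ndarray] = []
        for ki in range(k):
            group = splits[ki * r : (ki + 1) * r]
            u_hat = group[0]
            for u in group[1:]:
                u_hat = u_hat + u
            s = u_hat.mean(axis=(2, 3), keepdims=True)  # (B, c, 1, 1)
            logits = self.gates[ki](s)  # (B, r*c, 1, 1)
            B = logits.shape[0]
            logits = logits.reshape(B, r, c, 1, 1)
            if r > 1:
                a = logits.softmax(axis=1)
            else:
                a = logits.sigmoid()
            weights.append(a.data[:, :, :, 0, 0])
            v = group[0] * a.narrow(1, 0, 1).reshape(B, c, 1, 1)
            for i in range(1, r):
                v = v + group[i] * a.narrow(1, i, 1).reshape(B, c, 1, 1)
            outs.append(v)
        self.last_weights = np.stack(weights, axis=1)  # (B, k, r, c)
        return concat(outs, axis=1) if k > 1 else outs[0]


def split_attention(
    splits: list, radix: int, cardinal: int, module: SplitAttention | None = None
) -> Tensor:
    """Functional entry point; builds a freshly-initialized gate if needed."""
    if module is None:
        c = as_tensor(splits[0]).shape[1]
        module = SplitAttention(c, radix, cardinal)
    return module(splits)


# --------------------------------------------------------------------- blocks
@dataclass(frozen=True)
class BlockConfig:
    """Shape contract of one split-attention block.

    ``bottleneck_channels`` is the total width after the 1×1 reduce; it must
    divide evenly into cardinal·radix splits.
    """

    radix: int
    cardinal: int
    in_channels: int
    bottleneck_channels: int
    out_channels: int
    stride: int = 1
    conv: str = "conv"  # "conv" | "dsc"
    downsample: str = "pool"  # "pool" | "madm"
    attention: str = "split"  # "split" | "split_ca" | "split_clam"

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise InvalidConfigError("stride must be 1 or 2")
        if min(self.radix, self.cardinal, self.in_channels, self.out_channels) < 1:
            raise InvalidConfigError("dimensions must be positive")
        if self.bottleneck_channels % (self.radix * self.cardinal):
            raise InvalidConfigError(
                "bottleneck_channels must divide into cardinal*radix splits"
            )


def _norm_conv(c_in, c_out, kernel, stride, groups=1):
    return nn.Sequential(
        nn.Conv2d(c_in, c_out, kernel, stride=stride, padding=kernel // 2, groups=groups),
        nn.BatchNorm2d(c_out),
        nn.ReLU(),
    )


class SCMBlock(nn.Module):
    """Split-attention bottleneck with optional coordinate attention and
    multi-scale down-sampling (residual output Y = T(X) + V)."""

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        self.cfg = cfg
        r, k = cfg.radix, cfg.cardinal
        self.n_splits = r * k
        self.split_width = cfg.bottleneck_channels // self.n_splits
        gw = self.split_width * k  # group width entering the final 1x1

        if cfg.attention == "split_clam":
            self.attn = CLAM(cfg.in_channels)
        elif cfg.attention == "split_ca":
            self.attn = CoordinateAttention(cfg.in_channels)
        else:
            self.attn = None

        self.reduce = _norm_conv(cfg.in_channels, cfg.bottleneck_channels, 1, 1)

        if cfg.stride == 2 and cfg.downsample == "madm":
            self.spatial = nn.ModuleList(
                MADM(MadmConfig(self.split_width, self.split_width))
                for _ in range(self.n_splits)
            )
        elif cfg.conv == "dsc":
            self.spatial = DepthwiseSeparableConv(
                cfg.bottleneck_channels,
                cfg.bottleneck_channels,
                kernel=3,
                stride=cfg.stride,
                norm="post",
                pointwise_groups=self.n_splits,
            )
        else:
            self.spatial = _norm_conv(
                cfg.bottleneck_channels,
                cfg.bottleneck_channels,
                3,
                cfg.stride,
                groups=self.n_splits,
            )

        self.split_attn = SplitAttention(self.split_width, r, k)
        self.expand = nn.Sequential(
            nn.Conv2d(gw, cfg.out_channels, 1), nn.BatchNorm2d(cfg.out_channels)
        )

        if cfg.stride == 2:
            if cfg.downsample == "madm":
                self.residual = MADM(MadmConfig(cfg.in_channels, cfg.out_channels))
            else:
                self.residual = nn.Sequential(
                    nn.Conv2d(cfg.in_channels, cfg.out_channels, 1, stride=2),
                    nn.BatchNorm2d(cfg.out_channels),
                )
        elif cfg.in_channels != cfg.out_channels:
            self.residual = nn.Sequential(
                nn.Conv2d(cfg.in_channels, cfg.out_channels, 1),
                nn.BatchNorm2d(cfg.out_channels),
            )
        else:
            self.residual = nn.Identity()

    def main_branch(self, x: Tensor) -> Tensor:
        if self.attn is not None:
            x = self.attn(x)
        y = self.reduce(x)
        if isinstance(self.spatial, nn.ModuleList):
            parts = y.split(self.n_splits, axis=1)
            parts = [m(p) for m, p in zip(self.spatial, parts)]
        else:
            parts = self.spatial(y).split(self.n_splits, axis=1)
        v = self.split_attn(parts)
        return self.expand(v)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        t = self.residual(x)
        v = self.main_branch(x)
        if t.shape != v.shape:  # must be impossible by construction
            raise AssertionError(
                f"residual/main shape mismatch: {t.shape} vs {v.shape}"
            )
        return (t + v).relu()


def scm_block_forward(x, cfg: BlockConfig) -> Tensor:
    return SCMBlock(cfg)(x)


class ResBottleneck(nn.Module):
    """Canonical bottleneck residual block (the Scheme-1 reference)."""

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        planes = cfg.bottleneck_channels
        self.cfg = cfg
        self.conv1 = _norm_conv(cfg.in_channels, planes, 1, 1)
        if cfg.stride == 2 and cfg.downsample == "madm":
            self.conv2 = MADM(MadmConfig(planes, planes))
        elif cfg.conv == "dsc":
            self.conv2 = DepthwiseSeparableConv(
                planes, planes, kernel=3, stride=cfg.stride, norm="post"
            )
        else:
            self.conv2 = _norm_conv(planes, planes, 3, cfg.stride)
        self.conv3 = nn.Sequential(
            nn.Conv2d(planes, cfg.out_channels, 1), nn.BatchNorm2d(cfg.out_channels)
        )
        if cfg.stride != 1 or cfg.in_channels != cfg.out_channels:
            self.residual = nn.Sequential(
                nn.Conv2d(cfg.in_channels, cfg.out_channels, 1, stride=cfg.stride),
                nn.BatchNorm2d(cfg.out_channels),
            )
        else:
            self.residual = nn.Identity()

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        t = self.residual(x)
        v = self.conv3(self.conv2(self.conv1(x)))
        return (t + v).relu()


# -------------------------------------------------------------------- network
@dataclass(frozen=True)
class NetworkConfig:
    stage_depths: tuple[int, int, int, int] = (3, 4, 6, 3)
    stem_channels: int = 64
    num_classes: int = 4
    radix: int = 2
    cardinal: int = 1
    block: str = "scm"  # "res" | "resnest" | "scm"
    attention: str = "split_clam"  # "none" | "split" | "split_ca" | "split_clam"
    conv: str = "dsc"  # "conv" | "dsc"
    downsample: str = "madm"  # "pool" | "madm"
    base_width: int = 64

    def __post_init__(self):
        if len(self.stage_depths) != 4:
            raise InvalidConfigError("exactly four stage depths are required")
        if any(d < 1 for d in self.stage_depths):
            raise InvalidConfigError("stage depths must be positive")
        if self.block not in ("res", "resnest", "scm"):
            raise InvalidConfigError(f"unknown block {self.block!r}")
        if self.attention not in ("none", "split", "split_ca", "split_clam"):
            raise InvalidConfigError(f"unknown attention {self.attention!r}")
        if self.conv not in ("conv", "dsc"):
            raise InvalidConfigError(f"unknown conv {self.conv!r}")
        if self.downsample not in ("pool", "madm"):
            raise InvalidConfigError(f"unknown downsample {self.downsample!r}")
        if self.block == "res" and self.attention != "none":
            raise InvalidConfigError("the plain residual block carries no attention")
        if self.block != "res" and self.attention == "none":
            raise InvalidConfigError("split-attention blocks require attention != none")

    # convenience toggles mirroring the ablation grid columns
    @property
    def use_madm(self) -> bool:
        return self.downsample == "madm"

    @property
    def use_clam(self) -> bool:
        return self.attention == "split_clam"

    @property
    def use_dsc(self) -> bool:
        return self.conv == "dsc"


class Network(nn.Module):
    """Four-stage residual classifier: stem → stages → pooled linear head."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        stem = cfg.stem_channels
        if cfg.block == "scm":
            units: list[nn.Module] = [_norm_conv(3, stem, 3, 1)]
            if cfg.attention == "split_clam":
                units.append(CLAM(stem))
            elif cfg.attention == "split_ca":
                units.append(CoordinateAttention(stem))
            for _ in range(2):
                if cfg.downsample == "madm":
                    units.append(MADM(MadmConfig(stem, stem)))
                else:
                    units.append(nn.MaxPool2d(3, stride=2, padding=1))
            self.stem = nn.Sequential(*units)
        else:
            self.stem = nn.Sequential(
                nn.Conv2d(3, stem, 7, stride=2, padding=3),
                nn.BatchNorm2d(stem),
                nn.ReLU(),
                nn.MaxPool2d(3, stride=2, padding=1),
            )

        in_ch = stem
        for i in range(4):
            planes = cfg.base_width * (2**i)
            out_ch = planes * 4
            blocks: list[nn.Module] = []
            for j in range(cfg.stage_depths[i]):
                stride = 2 if (i > 0 and j == 0) else 1
                if cfg.block == "res":
                    bcfg = BlockConfig(
                        radix=1,
                        cardinal=1,
                        in_channels=in_ch,
                        bottleneck_channels=planes,
                        out_channels=out_ch,
                        stride=stride,
                        conv=cfg.conv,
                        downsample=cfg.downsample,
                        attention="split",
                    )
                    blocks.append(ResBottleneck(bcfg))
                else:
                    bcfg = BlockConfig(
                        radix=cfg.radix,
                        cardinal=cfg.cardinal,
                        in_channels=in_ch,
                        bottleneck_channels=planes * cfg.cardinal * cfg.radix,
                        out_channels=out_ch,
                        stride=stride,
                        conv=cfg.conv,
                        downsample=cfg.downsample,
                        attention=cfg.attention,
                    )
                    blocks.append(SCMBlock(bcfg))
                in_ch = out_ch
            setattr(self, f"stage{i + 1}", nn.Sequential(*blocks))

        self.pool = nn.GlobalAvgPool2d(keepdims=False)
        self.head = nn.Linear(in_ch, cfg.num_classes, bias=True)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        y = self.stem(x)
        for i in range(4):
            y = getattr(self, f"stage{i + 1}")(y)
        y = self.pool(y).reshape(y.shape[0], -1)
        return self.head(y)

    def predict_proba(self, x) -> np.ndarray:
        return self(x).softmax(axis=1).data


def build_network(cfg: NetworkConfig) -> Network:
    return Network(cfg)


def count_parameters(model: nn.Module) -> float:
    """Total trainable scalars, in millions rounded to three decimals."""
    return round(model.num_parameters() / 1e6, 3)


# ------------------------------------------------------------- ablation grid
# scheme id -> (block, attention, conv, downsample)
SCHEMES: dict[int, tuple[str, str, str, str]] = {
    1: ("res", "none", "conv", "pool"),
    2: ("resnest", "split", "conv", "pool"),
    3: ("resnest", "split_ca", "conv", "pool"),
    4: ("resnest", "split_clam", "conv", "pool"),
    5: ("resnest", "split", "dsc", "pool"),
    6: ("resnest", "split_ca", "dsc", "pool"),
    7: ("resnest", "split_clam", "dsc", "pool"),
    8: ("scm", "split", "conv", "pool"),
    9: ("scm", "split", "conv", "madm"),
    10: ("scm", "split_ca", "conv", "madm"),
    11: ("scm", "split_clam", "conv", "madm"),
    12: ("scm", "split", "dsc", "madm"),
    13: ("scm", "split_ca", "dsc", "madm"),
    14: ("scm", "split_clam", "dsc", "madm"),
}

PRESETS: dict[str, int] = {"resnet_ref": 1, "scmnet": 8, "mc_scmnet": 14}


def scheme_config(scheme: int, num_classes: int = 4, **overrides) -> NetworkConfig:
    if scheme not in SCHEMES:
        raise InvalidConfigError(
            f"unknown scheme {scheme}; valid ids: {sorted(SCHEMES)}"
        )
    block, attention, conv, downsample = SCHEMES[scheme]
    cfg = NetworkConfig(
        num_classes=num_classes,
        radix=1 if block == "res" else 2,
        cardinal=1,
        block=block,
        attention=attention,
        conv=conv,
        downsample=downsample,
    )
    return replace(cfg, **overrides) if overrides else cfg


def preset_config(name: str, num_classes: int = 4, **overrides) -> NetworkConfig:
    if name not in PRESETS:
        raise InvalidConfigError(
            f"unknown preset {name!r}; valid: {sorted(PRESETS)}"
        )
    return scheme_config(PRESETS[name], num_classes=num_classes, **overrides)
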