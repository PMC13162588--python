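"""Spatio-temporal attention gating for rank-5 video features (ST-CBAM).

Four sub-modules run in sequence over X in R^{B x C x T x H x W}:

  channel   Ac = sigmoid(bottleneck(GAP_THW(X)))       Yc = X  * Ac
  spatial   As = sigmoid(conv7x7([mean_C; max_C](Yc))) Ys = Yc * As
  temporal  At = sigmoid(conv3(conv3(GAP_HW(Ys))))     Yt = Ys * At
  joint     Ast = sigmoid(conv3(conv3(Yt)))            Y  = X + Yt * Ast

The first three stages are purely multiplicative gates; only the final joint
stage carries the residual connection back to the block input.  All gates
are sigmoid-bounded, so every weight lies strictly in (0, 1).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F

__all__ = [
    "ChannelAttention", "SpatialAttention", "TemporalAttention",
    "STJointAttention", "STCBAM",
]


def _bottleneck_width(channels: int, reduction: int) -> int:
    return max(channels // reduction, 1)


class ChannelAttention(nn.Module):
    """Squeeze (global average pool) -> 1x1x1 bottleneck -> sigmoid gate."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        mid = _bottleneck_width(channels, reduction)
        self.fc1 = nn.Conv3d(channels, mid, 1, rng=rng)
        self.fc2 = nn.Conv3d(mid, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        pooled = x.mean(axis=(2, 3, 4), keepdims=True)  # [B,C,1,1,1]
        ac = self.fc2(self.fc1(pooled).relu()).sigmoid()
        return ac, x * ac


class SpatialAttention(nn.Module):
    """Channel mean+max maps -> [1,7,7] conv -> sigmoid gate per (t,h,w)."""

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv3d(2, 1, (1, 7, 7), padding=(0, 3, 3), rng=rng)

    def forward(self, yc: Tensor) -> tuple[Tensor, Tensor]:
        mean_map = yc.mean(axis=1, keepdims=True)
        max_map = yc.max(axis=1, keepdims=True)
        as_ = self.conv(nn.concatenate([mean_map, max_map], axis=1)).sigmoid()
        return as_, yc * as_


class TemporalAttention(nn.Module):
    """Spatially pooled profile -> two [3,1,1] convs -> per-timestep gate."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        mid = _bottleneck_width(channels, reduction)
        self.conv1 = nn.Conv3d(channels, mid, (3, 1, 1), padding=(1, 0, 0), rng=rng)
        self.conv2 = nn.Conv3d(mid, 1, (3, 1, 1), padding=(1, 0, 0), rng=rng)

    def forward(self, ys: Tensor) -> tuple[Tensor, Tensor]:
        profile = ys.mean(axis=(3, 4), keepdims=True)  # [B,C,T,1,1]
        at = self.conv2(self.conv1(profile).relu()).sigmoid()  # [B,1,T,1,1]
        return at, ys * at


class STJointAttention(nn.Module):
    """Channel-compressing [3,1,1] convs -> full (t,h,w) gate -> residual."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        mid = _bottleneck_width(channels, reduction)
        self.conv1 = nn.Conv3d(channels, mid, (3, 1, 1), padding=(1, 0, 0), rng=rng)
        self.conv2 = nn.Conv3d(mid, 1, (3, 1, 1), padding=(1, 0, 0), rng=rng)

    def forward(self, x: Tensor, yt: Tensor) -> Tensor:
        if x.shape != yt.shape:
            raise ValueError(f"shape mismatch: {x.shape} vs {yt.shape}")
        ast = self.conv2(self.conv1(yt).relu()).sigmoid()  # [B,1,T,H,W]
        self.last_weights = ast  # exposed for inspection/tests
        return x + yt * ast


class STCBAM(nn.Module):
    """The four attention stages chained in order; shape-preserving."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(rng=rng)
        self.temporal = TemporalAttention(channels, reduction, rng=rng)
        self.joint = STJointAttention(channels, reduction, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _, yc = self.channel(x)
        _, ys = self.spatial(yc)
        _, yt = self.temporal(ys)
        return self.joint(x, yt)
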