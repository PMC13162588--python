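"""Dual-pathway 3D-residual video backbone with attention-gated lateral fusion.

Two pathways process the same clip at different rates: the slow pathway sees
``t_slow`` frames sampled every ``tau`` raw frames at full channel width; the
fast pathway sees ``alpha`` times more frames at ``beta`` times the width
(defaults tau=8, alpha=4, beta=1/8).  Both are bottleneck 3D ResNets (depth
50 or 101).  After the stem and after each of res2..res4 a FastToSlow block
carries fast-path features into the slow path: a time-strided
[fusion_kernel, 1, 1] convolution collapses the temporal rate mismatch and
compresses channels by ``fusion_compression_r``, the result is recalibrated
by an ST-CBAM gate, aligned to the slow width with a pointwise convolution,
and added element-wise.  Every residual block in res3 and res4 is followed
by an ST-CBAM block (a "STCBAMRes" block) on both pathways by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import STCBAM
from .nn import Tensor
from .nn import functional as F

__all__ = [
    "BackboneConfig", "PathwayFeatures", "FastToSlow", "SlowFastBackbone",
    "build_backbone",
]

SUPPORTED_DEPTHS = {50: (3, 4, 6, 3), 101: (3, 4, 23, 3)}


@dataclass(frozen=True)
class BackboneConfig:
    tau: int = 8
    alpha: int = 4
    beta: float = 1 / 8
    depth: int = 50
    fusion_kernel: int = 5
    fusion_compression_r: float = 0.5
    t_slow: int = 8
    base_width: int = 64          # slow-path stem channels
    stage_blocks: tuple | None = None  # override depth's block counts
    stcbam_slow: bool = True
    stcbam_fast: bool = True
    attention_reduction: int = 16
    norm: str = "batch"  # "batch" (reference protocol) or "group" (small batches)

    def __post_init__(self):
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.tau % self.alpha:
            raise ValueError("tau must be divisible by alpha")
        if self.fusion_kernel % 2 == 0:
            raise ValueError("fusion_kernel must be odd")
        if self.norm not in ("batch", "group"):
            raise ValueError("norm must be 'batch' or 'group'")
        if self.depth not in SUPPORTED_DEPTHS:
            raise ValueError(
                f"unsupported depth {self.depth}; choose one of "
                f"{sorted(SUPPORTED_DEPTHS)}")

    @property
    def blocks(self) -> tuple:
        return tuple(self.stage_blocks or SUPPORTED_DEPTHS[self.depth])


@dataclass
class PathwayFeatures:
    """Final-stage feature maps of both pathways."""

    slow: Tensor  # [B, C_slow, T_slow, H, W]
    fast: Tensor  # [B, C_fast, alpha * T_slow, H, W]


def _fast_width(c_slow: int, beta: float) -> int:
    return max(int(round(c_slow * beta)), 1)


def _norm3d(kind: str, channels: int) -> nn.Module:
    if kind == "group":
        return nn.GroupNorm3d(channels)
    return nn.BatchNorm3d(channels)


class Bottleneck(nn.Module):
    """1x1x1 (optionally temporal) -> 1x3x3 -> 1x1x1 residual block; the last
    normalization scale starts at zero so fresh blocks begin near identity."""

    def __init__(self, in_ch: int, out_ch: int, spatial_stride: int,
                 temporal_kernel: int, attention: STCBAM | None,
                 rng: np.random.Generator, norm: str = "batch"):
        super().__init__()
        mid = max(out_ch // 4, 1)
        tk = temporal_kernel
        self.conv1 = nn.Conv3d(in_ch, mid, (tk, 1, 1), padding=(tk // 2, 0, 0),
                               bias=False, rng=rng)
        self.bn1 = _norm3d(norm, mid)
        self.conv2 = nn.Conv3d(mid, mid, (1, 3, 3),
                               stride=(1, spatial_stride, spatial_stride),
                               padding=(0, 1, 1), bias=False, rng=rng)
        self.bn2 = _norm3d(norm, mid)
        self.conv3 = nn.Conv3d(mid, out_ch, 1, bias=False, rng=rng)
        self.bn3 = _norm3d(norm, out_ch)
        self.bn3.weight.data[:] = 0.0
        if in_ch != out_ch or spatial_stride != 1:
            self.down_conv = nn.Conv3d(in_ch, out_ch, 1,
                                       stride=(1, spatial_stride, spatial_stride),
                                       bias=False, rng=rng)
            self.down_bn = _norm3d(norm, out_ch)
        else:
            self.down_conv = None
        self.attention = attention

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        short = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        out = (out + short).relu()
        if self.attention is not None:
            out = self.attention(out)
        return out


class Pathway(nn.Module):
    """Stem plus res2..res5 for one rate branch."""

    def __init__(self, width: int, blocks: tuple, temporal_kernels: tuple,
                 stem_temporal: int, use_stcbam: bool, reduction: int,
                 rng: np.random.Generator, norm: str = "batch"):
        super().__init__()
        self.stem_conv = nn.Conv3d(3, width, (stem_temporal, 7, 7),
                                   stride=(1, 2, 2),
                                   padding=(stem_temporal // 2, 3, 3),
                                   bias=False, rng=rng)
        self.stem_bn = _norm3d(norm, width)
        self.stage_channels = [width * 4 * 2 ** i for i in range(4)]
        self.stages = nn.ModuleList()
        in_ch = width
        for i, (n_blocks, tk) in enumerate(zip(blocks, temporal_kernels)):
            out_ch = self.stage_channels[i]
            stage = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and i > 0) else 1
                attn = (STCBAM(out_ch, reduction, rng=rng)
                        if use_stcbam and i in (1, 2) else None)  # res3, res4
                stage.append(Bottleneck(in_ch, out_ch, stride, tk, attn, rng,
                                        norm=norm))
                in_ch = out_ch
            self.stages.append(nn.Sequential(*stage))

    def stem(self, x: Tensor) -> Tensor:
        out = self.stem_bn(self.stem_conv(x)).relu()
        return F.maxpool3d(out, kernel=(1, 3, 3), stride=(1, 2, 2),
                           padding=(0, 1, 1))


class FastToSlow(nn.Module):
    """Lateral fusion: time-strided conv, channel compression, ST-CBAM gate,
    width alignment, element-wise addition into the slow path."""

    def __init__(self, c_fast: int, c_slow: int, alpha: int, kernel: int,
                 compression_r: float, reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        self.alpha = alpha
        c_mid = max(int(round(c_fast * compression_r)), 1)
        self.compressed_channels = c_mid
        self.conv = nn.Conv3d(c_fast, c_mid, (kernel, 1, 1),
                              stride=(alpha, 1, 1),
                              padding=((kernel - 1) // 2, 0, 0), rng=rng)
        self.attn = STCBAM(c_mid, reduction, rng=rng)
        self.align = nn.Conv3d(c_mid, c_slow, 1, rng=rng)

    def forward(self, fast_feat: Tensor, slow_feat: Tensor) -> Tensor:
        t_fast, t_slow = fast_feat.shape[2], slow_feat.shape[2]
        if t_fast != self.alpha * t_slow:
            raise ValueError(
                f"temporal mismatch: T_fast={t_fast} is not "
                f"alpha={self.alpha} times T_slow={t_slow}")
        x = self.conv(fast_feat)
        x = self.attn(x)
        x = self.align(x)
        if x.shape != slow_feat.shape:
            raise ValueError(f"fusion shape {x.shape} != slow {slow_feat.shape}")
        return slow_feat + x


class SlowFastBackbone(nn.Module):
    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        w_slow = cfg.base_width
        w_fast = _fast_width(w_slow, cfg.beta)
        blocks = cfg.blocks
        # slow path models appearance: temporal kernels only in res4/res5;
        # fast path models motion: temporal kernels everywhere incl. stem
        self.slow = Pathway(w_slow, blocks, (1, 1, 3, 3), 1,
                            cfg.stcbam_slow, cfg.attention_reduction, rng,
                            norm=cfg.norm)
        self.fast = Pathway(w_fast, blocks, (3, 3, 3, 3), 5,
                            cfg.stcbam_fast, cfg.attention_reduction, rng,
                            norm=cfg.norm)
        fuse_points = [w_fast] + self.fast.stage_channels[:3]
        slow_points = [w_slow] + self.slow.stage_channels[:3]
        self.fusions = nn.ModuleList([
            FastToSlow(cf, cs, cfg.alpha, cfg.fusion_kernel,
                       cfg.fusion_compression_r, cfg.attention_reduction, rng)
            for cf, cs in zip(fuse_points, slow_points)
        ])

    @property
    def out_channels(self) -> tuple[int, int]:
        return self.slow.stage_channels[-1], self.fast.stage_channels[-1]

    def forward(self, slow_clip: Tensor, fast_clip: Tensor) -> PathwayFeatures:
        if fast_clip.shape[2] != self.cfg.alpha * slow_clip.shape[2]:
            raise ValueError(
                "clip temporal ratio must equal alpha "
                f"({fast_clip.shape[2]} vs {self.cfg.alpha} x {slow_clip.shape[2]})")
        s = self.slow.stem(slow_clip)
        f = self.fast.stem(fast_clip)
        s = self.fusions[0](f, s)
        for i in range(4):
            s = self.slow.stages[i](s)
            f = self.fast.stages[i](f)
            if i < 3:
                s = self.fusions[i + 1](f, s)
        return PathwayFeatures(slow=s, fast=f)


def build_backbone(cfg: BackboneConfig,
                   rng: np.random.Generator | None = None) -> SlowFastBackbone:
    return SlowFastBackbone(cfg, rng=rng)


def tiny_config(**overrides) -> BackboneConfig:
    """CPU-scale preset: depth-50 layout with one block per stage and an
    8-channel stem, for desk-size experiments and tests."""
    defaults = dict(depth=50, stage_blocks=(1, 1, 1, 1), base_width=8,
                    t_slow=4, attention_reduction=4, norm="group")
    defaults.update(overrides)
    return BackboneConfig(**defaults)
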