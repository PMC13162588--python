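"""Bidirectional Adaptive Fusion (BAF) of slow and fast pathway features.

Applied once before the detection head.  Both paths are projected into a
shared space of half the slow width with pointwise convolutions (the fast
projection is trilinearly resampled to the slow extents when rates differ).
A [3, 1, 1] temporal convolution enhances motion in the fast projection.
A softmax over exactly two pooled logits yields per-sample path weights
A_s + A_f = 1, mixing the projections; a 3x3x3 neighborhood convolution
restores the slow width, and the result re-enters the slow path through a
learnable residual scalar initialized at 0.1 — so a fresh module perturbs
the slow features only mildly, and a zero weight is exactly the identity.

The reverse (slow-to-fast) injection is intentionally absent: only the slow
path is enriched; the fast map passes to the head untouched.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["BAF", "trilinear_resize"]


def _axis_linear_resize(x: Tensor, axis: int, new_len: int) -> Tensor:
    """Differentiable linear interpolation along one axis (half-pixel centers)."""
    old_len = x.shape[axis]
    if old_len == new_len:
        return x
    src = (np.arange(new_len) + 0.5) * (old_len / new_len) - 0.5
    src = np.clip(src, 0.0, old_len - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, old_len - 1)
    w = src - i0
    sl = [slice(None)] * len(x.shape)
    sl0, sl1 = list(sl), list(sl)
    sl0[axis], sl1[axis] = i0, i1
    wshape = [1] * len(x.shape)
    wshape[axis] = new_len
    w = Tensor(w.reshape(wshape))
    return x[tuple(sl0)] * (1.0 - w) + x[tuple(sl1)] * w


def trilinear_resize(x: Tensor, target_tHW: tuple[int, int, int]) -> Tensor:
    """Resample a [B, C, T, H, W] tensor to the target (T, H, W) extents.

    Separable linear interpolation per axis; the identity (bit-exact) when
    extents already match.
    """
    for axis, new_len in zip((2, 3, 4), target_tHW):
        x = _axis_linear_resize(x, axis, int(new_len))
    return x


class BAF(nn.Module):
    def __init__(self, c_slow: int, c_fast: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c_slow < 2:
            raise ValueError("slow channel count must be at least 2")
        rng = rng or np.random.default_rng()
        c_half = c_slow // 2
        self.c_half = c_half
        self.proj_slow = nn.Conv3d(c_slow, c_half, 1, rng=rng)
        self.proj_fast = nn.Conv3d(c_fast, c_half, 1, rng=rng)
        self.motion = nn.Conv3d(c_half, c_half, (3, 1, 1), padding=(1, 0, 0),
                                rng=rng)
        hidden = max((2 * c_half) // 4, 1)
        self.att_fc1 = nn.Linear(2 * c_half, hidden, rng=rng)
        self.att_fc2 = nn.Linear(hidden, 2, rng=rng)
        self.fuse_conv = nn.Conv3d(c_half, c_slow, (3, 3, 3),
                                   padding=(1, 1, 1), rng=rng)
        self.res_weight = nn.Parameter(np.array(0.1))

    # ---------------------------------------------------------------- stages
    def project_paths(self, fs: Tensor, ff: Tensor) -> tuple[Tensor, Tensor]:
        fs_p = self.proj_slow(fs)
        ff_p = self.proj_fast(ff)
        if ff_p.shape[2:] != fs_p.shape[2:]:
            ff_p = trilinear_resize(ff_p, fs_p.shape[2:])
        return fs_p, ff_p

    def enhance_motion(self, ff_p: Tensor) -> Tensor:
        return self.motion(ff_p)

    def path_attention(self, fs_p: Tensor, ff_enh: Tensor,
                       ) -> tuple[Tensor, Tensor, Tensor]:
        if fs_p.shape != ff_enh.shape:
            raise ValueError(
                f"projected shapes differ: {fs_p.shape} vs {ff_enh.shape}")
        pooled = nn.concatenate([fs_p, ff_enh], axis=1).mean(axis=(2, 3, 4))
        logits = self.att_fc2(self.att_fc1(pooled).relu())  # [B, 2]
        coeff = logits.softmax(axis=1)
        a_s = coeff[:, 0:1].reshape(-1, 1, 1, 1, 1)
        a_f = coeff[:, 1:2].reshape(-1, 1, 1, 1, 1)
        f_att = fs_p * a_s + ff_enh * a_f
        return a_s, a_f, f_att

    def fuse_residual(self, fs: Tensor, f_att: Tensor) -> Tensor:
        f_fusion = self.fuse_conv(f_att)
        if f_fusion.shape != fs.shape:
            raise ValueError(
                f"fused shape {f_fusion.shape} misaligned with slow {fs.shape}")
        return fs + f_fusion * self.res_weight

    def forward(self, fs: Tensor, ff: Tensor) -> Tensor:
        fs_p, ff_p = self.project_paths(fs, ff)
        ff_enh = self.enhance_motion(ff_p)
        _, _, f_att = self.path_attention(fs_p, ff_enh)
        return self.fuse_residual(fs, f_att)
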