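"""Structured operations on video tensors: 3D convolution, pooling, region
sampling and class-probability gathering.

Convolution is implemented with stride-tricks sliding windows plus einsum in
the forward pass; the input gradient is scattered back with a short loop over
kernel offsets (kernels here are at most 7x7 spatially, 5 temporally, so the
loop is cheap relative to the einsum work).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = ["conv3d", "maxpool3d", "roi_pool_bilinear", "gather_rows", "dropout"]


def _triple(v):
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError("expected a length-3 tuple")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1, 1), padding=(0, 0, 0)) -> Tensor:
    """3D cross-correlation of x [B,Cin,T,H,W] with w [Cout,Cin,kt,kh,kw]."""
    st, sh, sw = _triple(stride)
    pt, ph, pw = _triple(padding)
    kt, kh, kw = w.data.shape[2:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::st, ::sh, ::sw]  # [B,Cin,To,Ho,Wo,kt,kh,kw]
    out = np.einsum("bithwxyz,oixyz->bothw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1, 1)
    B, _, To, Ho, Wo = out.shape

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("bithwxyz,bothw->oixyz", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for it in range(kt):
                for ih in range(kh):
                    for iw in range(kw):
                        contrib = np.einsum(
                            "bothw,oi->bithw", g, w.data[:, :, it, ih, iw],
                            optimize=True,
                        )
                        gxp[:, :,
                            it:it + To * st:st,
                            ih:ih + Ho * sh:sh,
                            iw:iw + Wo * sw:sw] += contrib
            T, H, W = x.data.shape[2:]
            x._accum(gxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def maxpool3d(x: Tensor, kernel=(1, 3, 3), stride=(1, 2, 2),
              padding=(0, 1, 1)) -> Tensor:
    """Max pooling over [B,C,T,H,W] windows; ties route to the first maximum."""
    kt, kh, kw = _triple(kernel)
    st, sh, sw = _triple(stride)
    pt, ph, pw = _triple(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)),
                constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::st, ::sh, ::sw]
    B, C, To, Ho, Wo = win.shape[:5]
    flat = win.reshape(B, C, To, Ho, Wo, -1)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        it, ih, iw = np.unravel_index(arg, (kt, kh, kw))
        bi, ci, ti, hi, wi = np.indices(arg.shape, sparse=False)
        np.add.at(gxp, (bi, ci, ti * st + it, hi * sh + ih, wi * sw + iw), g)
        T, H, W = x.data.shape[2:]
        x._accum(gxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W])

    return Tensor._make(out, (x,), backward)


def roi_pool_bilinear(fmap: Tensor, boxes: np.ndarray, batch_index: np.ndarray,
                      resolution: int) -> Tensor:
    """Sample an RxR grid of bilinear values per normalized box.

    fmap: [B, C, H, W] (time already pooled); boxes: [N, 4] normalized
    (x1, y1, x2, y2); batch_index: [N] int.  One sample point per grid cell,
    at the cell center.  Degenerate boxes collapse to a single repeated point.
    Returns [N, C, R, R].
    """
    boxes = np.asarray(boxes, dtype=np.float64)
    batch_index = np.asarray(batch_index, dtype=np.intp)
    N = boxes.shape[0]
    B, C, H, W = fmap.data.shape
    R = int(resolution)
    if N == 0:
        return Tensor(np.zeros((0, C, R, R)))
    # continuous sample coordinates in feature space
    x1 = boxes[:, 0] * W
    y1 = boxes[:, 1] * H
    x2 = boxes[:, 2] * W
    y2 = boxes[:, 3] * H
    cell = (np.arange(R) + 0.5) / R
    sx = x1[:, None] + cell[None, :] * np.maximum(x2 - x1, 1e-9)[:, None]  # [N,R]
    sy = y1[:, None] + cell[None, :] * np.maximum(y2 - y1, 1e-9)[:, None]
    # bilinear neighbours, clamped to the map
    sx = np.clip(sx - 0.5, 0.0, W - 1.0)
    sy = np.clip(sy - 0.5, 0.0, H - 1.0)
    x0 = np.floor(sx).astype(np.intp)
    y0 = np.floor(sy).astype(np.intp)
    x1i = np.minimum(x0 + 1, W - 1)
    y1i = np.minimum(y0 + 1, H - 1)
    fx = sx - x0
    fy = sy - y0

    bi = batch_index[:, None, None]                       # [N,1,1]
    gy0 = y0[:, :, None]                                  # [N,R,1]
    gy1 = y1i[:, :, None]
    gx0 = x0[:, None, :]                                  # [N,1,R]
    gx1 = x1i[:, None, :]
    wy = fy[:, :, None]
    wx = fx[:, None, :]
    w00 = (1 - wy) * (1 - wx)
    w01 = (1 - wy) * wx
    w10 = wy * (1 - wx)
    w11 = wy * wx

    d = fmap.data
    out = (d[bi, :, gy0, gx0] * w00[..., None]
           + d[bi, :, gy0, gx1] * w01[..., None]
           + d[bi, :, gy1, gx0] * w10[..., None]
           + d[bi, :, gy1, gx1] * w11[..., None])        # [N,R,R,C]
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(g):
        if not fmap.requires_grad:
            return
        gf = np.zeros_like(d)
        gperm = g.transpose(0, 2, 3, 1)                   # [N,R,R,C]
        np.add.at(gf, (bi, slice(None), gy0, gx0), gperm * w00[..., None])
        np.add.at(gf, (bi, slice(None), gy0, gx1), gperm * w01[..., None])
        np.add.at(gf, (bi, slice(None), gy1, gx0), gperm * w10[..., None])
        np.add.at(gf, (bi, slice(None), gy1, gx1), gperm * w11[..., None])
        fmap._accum(gf)

    return Tensor._make(out, (fmap,), backward)


def gather_rows(x: Tensor, col_index: np.ndarray) -> Tensor:
    """Select x[i, col_index[i]] per row -> vector of length N."""
    col_index = np.asarray(col_index, dtype=np.intp)
    rows = np.arange(x.data.shape[0])
    out = x.data[rows, col_index]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (rows, col_index), g)
            x._accum(full)

    return Tensor._make(out, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * as_tensor(mask)
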