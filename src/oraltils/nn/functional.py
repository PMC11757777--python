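"""Convolution primitives for the autodiff engine (im2col based)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor

__all__ = ["conv2d", "depthwise_conv2d", "conv_transpose2d"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """View an (N, C, H, W) array as (N, C, kh, kw, Ho, Wo) sliding windows."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    return as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )


def _col_scatter(
    g_windows: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int, stride: int
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add window grads back to the image."""
    n, c, h, w = x_shape
    ho, wo = g_windows.shape[-2:]
    gx = np.zeros(x_shape, np.float32)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += g_windows[
                :, :, i, j
            ]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """Standard cross-correlation: x (N,C,H,W) * w (O,C,kh,kw) -> (N,O,Ho,Wo)."""
    o, c, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = _im2col(xp, kh, kw, stride)
    n = x.shape[0]
    ho, wo = windows.shape[-2:]
    cols = windows.reshape(n, c * kh * kw, ho * wo)
    out = np.matmul(w.data.reshape(o, -1), cols).reshape(n, o, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(n, o, ho * wo)
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", gm, cols, optimize=True)
            w._accumulate(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(w.data.reshape(o, -1).T, gm)  # (N, C*kh*kw, L)
            gwin = gcols.reshape(n, c, kh, kw, ho, wo)
            gxp = _col_scatter(gwin, xp.shape, kh, kw, stride)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._make(out, parents, backward)


def depthwise_conv2d(
    x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0
) -> Tensor:
    """Per-channel convolution: x (N,C,H,W) * w (C,kh,kw) -> (N,C,Ho,Wo)."""
    c, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = _im2col(xp, kh, kw, stride)  # (N, C, kh, kw, Ho, Wo)
    out = np.einsum("ncijhw,cij->nchw", windows, w.data, optimize=True)
    if b is not None:
        out = out + b.data.reshape(1, c, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    ho, wo = out.shape[-2:]

    def backward(g):
        if w.requires_grad:
            gw = np.einsum("nchw,ncijhw->cij", g, windows, optimize=True)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros(xp.shape, np.float32)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                        g * w.data[None, :, i, j, None, None]
                    )
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._make(out, parents, backward)


def conv_transpose2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    stride: int = 2,
    padding: int = 1,
    output_padding: int = 1,
) -> Tensor:
    """Transposed convolution, built from dilation + flipped-kernel conv.

    ``w`` has shape (C_in, C_out, kh, kw).  Output spatial size is
    ``(in - 1) * stride - 2 * padding + k + output_padding`` — with the
    default (k=3, stride=2, padding=1, output_padding=1) this exactly
    doubles the resolution.
    """
    kh = w.shape[2]
    xd = x.dilate2d(stride)
    edge = kh - 1 - padding
    if edge < 0:
        raise ValueError("padding larger than kernel-1 is not supported")
    xd = xd.pad2d(edge, edge + output_padding, edge, edge + output_padding)
    w_conv = w.flip2d().transpose(1, 0, 2, 3)  # (C_out, C_in, kh, kw)
    out = conv2d(xd, w_conv, None, stride=1, padding=0)
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1)
    return out
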