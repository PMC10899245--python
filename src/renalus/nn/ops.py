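"""Convolution primitives on NumPy arrays (NCHW, float32).

Strided convolution is implemented with ``sliding_window_view`` + one BLAS
matmul (im2col); the transposed convolution is its exact adjoint, built
from the same two building blocks run in the opposite direction.  The
kernel-offset scatter loop (col2im) runs K*K vectorised slice-adds, which
keeps everything inside NumPy without per-pixel Python work.

Shape conventions: conv weights are (C_out, C_in, K, K); transposed-conv
weights are (C_in, C_out, K, K).  'Same' geometry for odd K: pad (K-1)//2,
and output_padding stride-1 so a stride-2 transposed conv exactly doubles
the spatial size.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (col, (Ho, Wo)) with col of shape (N*Ho*Wo, C*K*K)."""
    xp = _pad_hw(x, pad)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(col), (ho, wo)


def _col2im(g6: np.ndarray, out_hw, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add (N, C, K, K, Ho, Wo) into (N, C, H, W)."""
    n, c, k, _, ho, wo = g6.shape
    h, w = out_hw
    hbuf = max((ho - 1) * stride + k, h + 2 * pad)
    wbuf = max((wo - 1) * stride + k, w + 2 * pad)
    buf = np.zeros((n, c, hbuf, wbuf), dtype=g6.dtype)
    hs, ws = (ho - 1) * stride + 1, (wo - 1) * stride + 1
    for ki in range(k):
        for kj in range(k):
            buf[:, :, ki : ki + hs : stride, kj : kj + ws : stride] += g6[:, :, ki, kj]
    return buf[:, :, pad : pad + h, pad : pad + w]


def conv2d_forward(x, weight, bias, stride: int, pad: int):
    """y = conv(x, W) + b.  Returns (y, cache) for the backward pass."""
    co, ci, k, _ = weight.shape
    col, (ho, wo) = _im2col(x, k, stride, pad)
    y = col @ weight.reshape(co, ci * k * k).T
    if bias is not None:
        y += bias
    n = x.shape[0]
    y = y.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    cache = (col, x.shape, (ho, wo))
    return np.ascontiguousarray(y), cache


def conv2d_backward(gy, weight, cache, stride: int, pad: int):
    """Gradients (gx, gW, gb) of conv2d_forward."""
    col, x_shape, (ho, wo) = cache
    n, ci, h, w = x_shape
    co, _, k, _ = weight.shape
    gyf = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(n * ho * wo, co)
    gw = (gyf.T @ col).reshape(co, ci, k, k)
    gb = gyf.sum(axis=0)
    gcol = gyf @ weight.reshape(co, ci * k * k)
    g6 = gcol.reshape(n, ho, wo, ci, k, k).transpose(0, 3, 4, 5, 1, 2)
    gx = _col2im(np.ascontiguousarray(g6), (h, w), stride, pad)
    return gx, gw, gb


def conv_transpose2d_forward(x, weight, bias, stride: int, pad: int, out_pad: int):
    """Transposed convolution; weight (C_in, C_out, K, K).

    Output spatial size: (H - 1) * stride - 2 * pad + K + out_pad.
    """
    n, ci, h, w = x.shape
    _, co, k, _ = weight.shape
    hout = (h - 1) * stride - 2 * pad + k + out_pad
    wout = (w - 1) * stride - 2 * pad + k + out_pad
    xm = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n * h * w, ci)
    g = xm @ weight.reshape(ci, co * k * k)
    g6 = g.reshape(n, h, w, co, k, k).transpose(0, 3, 4, 5, 1, 2)
    y = _col2im(np.ascontiguousarray(g6), (hout, wout), stride, pad)
    if bias is not None:
        y += bias[None, :, None, None]
    cache = (xm, x.shape)
    return y, cache


def conv_transpose2d_backward(gy, weight, cache, stride: int, pad: int):
    """Gradients (gx, gW, gb) of conv_transpose2d_forward."""
    xm, x_shape = cache
    n, ci, h, w = x_shape
    _, co, k, _ = weight.shape
    col_gy, (ho, wo) = _im2col(gy, k, stride, pad)
    assert (ho, wo) == (h, w), "transposed-conv geometry mismatch"
    gx = col_gy @ weight.reshape(ci, co * k * k).T
    gx = gx.reshape(n, h, w, ci).transpose(0, 3, 1, 2)
    gw = (xm.T @ col_gy).reshape(ci, co, k, k)
    gb = gy.sum(axis=(0, 2, 3))
    return np.ascontiguousarray(gx), gw, gb
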