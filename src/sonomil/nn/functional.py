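"""Composite and convolutional operations on :class:`~sonomil.nn.Tensor`."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "avg_pool2d_half",
    "global_avg_pool",
    "pad2d",
    "softmax",
    "dropout",
]


def pad2d(x: Tensor, padding: int) -> Tensor:
    """Zero-pad the last two (spatial) axes symmetrically."""
    if padding == 0:
        return x
    p = padding
    out_data = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))

    def backward(g):
        return (g[:, :, p:-p, p:-p],)

    return Tensor._from_op(out_data, (x,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation). ``x``: [N,Cin,H,W]; ``w``: [Cout,Cin,kh,kw]."""
    xp = pad2d(x, padding)
    kh, kw = w.shape[2], w.shape[3]
    s = stride
    xd, wd = xp.data, w.data
    win = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # win: [N, Cin, Ho, Wo, kh, kw]
    out_data = np.tensordot(win, wd, axes=([1, 4, 5], [1, 2, 3]))  # [N,Ho,Wo,Cout]
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    n, _, ho, wo = out_data.shape

    def backward(g):
        # g: [N, Cout, Ho, Wo]
        gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # [Cout,Cin,kh,kw]
        gx = np.zeros_like(xd)
        for i in range(kh):
            for j in range(kw):
                contrib = np.tensordot(g, wd[:, :, i, j], axes=([1], [0]))  # [N,Ho,Wo,Cin]
                gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += contrib.transpose(0, 3, 1, 2)
        return gx, gw.astype(wd.dtype)

    out = Tensor._from_op(out_data, (xp, w), backward)
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1)
    return out


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling with -inf padding so padded cells are never selected."""
    k, s, p = kernel, stride, padding
    xd = x.data
    if p:
        xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    win = sliding_window_view(xd, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    n, c, ho, wo = win.shape[:4]
    flat = win.reshape(n, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gxp = np.zeros_like(xd)
        ni, ci, yi, xi = np.ogrid[:n, :c, :ho, :wo]
        rows = yi * s + idx // k
        cols = xi * s + idx % k
        np.add.at(gxp, (ni, ci, rows, cols), g)
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        return (gxp,)

    return Tensor._from_op(out_data, (x,), backward)


def avg_pool2d_half(x: Tensor) -> Tensor:
    """0.5x bilinear downsample with the corner-excluding convention.

    At exactly scale 0.5 the corner-excluding (``align_corners=False``)
    bilinear kernel samples each output pixel at the centre of a 2x2 input
    block, i.e. it reduces to 2x2 average pooling; H and W must be even.
    """
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(
            f"feature map spatial size {h}x{w} must be even for the 0.5x downsample"
        )
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def global_avg_pool(x: Tensor) -> Tensor:
    """[N,C,H,W] -> [N,C] channel-wise spatial mean."""
    return x.mean(axis=(2, 3))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilised softmax along ``axis``."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(keep)
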