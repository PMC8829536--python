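"""Minimal NumPy neural-net primitives (internal).

im2col-based 2-D convolution with forward and backward passes, the few
activations the package needs, and SGD with momentum.  Arrays follow the
(N, C, H, W) layout.  This is deliberately small: just enough to train
the toy dense detector and to run the DCT encoders on a CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "im2col", "col2im", "conv2d", "conv2d_backward",
    "sigmoid", "relu", "SGDMomentum",
]


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Unfold (N, C, H, W) into (N, out_h, out_w, C*kh*kw) patches."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_h = _out_size(h, kh, stride, pad)
    out_w = _out_size(w, kw, stride, pad)
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, out_h, out_w, kh, kw),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    # -> (N, out_h, out_w, C, kh, kw) -> flatten patch dims
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h, out_w, -1)


def col2im(cols: np.ndarray, x_shape, kh: int, kw: int,
           stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back to an image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out_h = _out_size(h, kh, stride, pad)
    out_w = _out_size(w, kw, stride, pad)
    x = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, out_h, out_w, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + stride * out_h:stride, j:j + stride * out_w:stride] += \
                cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if pad:
        x = x[:, :, pad:hp - pad, pad:wp - pad]
    return x


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None,
           stride: int = 1, pad: int = 0, groups: int = 1):
    """Grouped 2-D convolution.  Returns (output, cache) for backward.

    weight has shape (C_out, C_in/groups, kh, kw).
    """
    n, c_in, h, w = x.shape
    c_out, c_in_g, kh, kw = weight.shape
    if c_in != c_in_g * groups:
        raise ValueError("channel/group mismatch")
    if groups == 1:
        cols = im2col(x, kh, kw, stride, pad)       # (N, oh, ow, C*kh*kw)
        out = cols @ weight.reshape(c_out, -1).T    # (N, oh, ow, C_out)
        cache = (cols, x.shape, weight.shape, stride, pad, groups)
    else:
        xg = x.reshape(n, groups, c_in // groups, h, w)
        wg = weight.reshape(groups, c_out // groups, c_in_g, kh, kw)
        outs, cols_list = [], []
        for g in range(groups):
            cols = im2col(xg[:, g], kh, kw, stride, pad)
            outs.append(cols @ wg[g].reshape(c_out // groups, -1).T)
            cols_list.append(cols)
        out = np.concatenate(outs, axis=-1)
        cache = (cols_list, x.shape, weight.shape, stride, pad, groups)
    if bias is not None:
        out = out + bias
    return out.transpose(0, 3, 1, 2), cache


def conv2d_backward(dout: np.ndarray, cache, weight: np.ndarray,
                    need_dx: bool = True):
    """Gradients of conv2d.  Returns (dx, dweight, dbias)."""
    cols, x_shape, w_shape, stride, pad, groups = cache
    c_out, c_in_g, kh, kw = w_shape
    dy = dout.transpose(0, 2, 3, 1)                 # (N, oh, ow, C_out)
    dbias = dy.sum(axis=(0, 1, 2))
    if groups == 1:
        dw = np.tensordot(dy, cols, axes=([0, 1, 2], [0, 1, 2]))
        dweight = dw.reshape(w_shape)
        dx = None
        if need_dx:
            dcols = dy @ weight.reshape(c_out, -1)
            dx = col2im(dcols, x_shape, kh, kw, stride, pad)
        return dx, dweight, dbias
    n, c_in, h, w = x_shape
    cog = c_out // groups
    wg = weight.reshape(groups, cog, c_in_g, kh, kw)
    dweight = np.empty_like(weight).reshape(groups, cog, c_in_g, kh, kw)
    dxs = []
    for g in range(groups):
        dyg = dy[..., g * cog:(g + 1) * cog]
        dweight[g] = np.tensordot(
            dyg, cols[g], axes=([0, 1, 2], [0, 1, 2])
        ).reshape(cog, c_in_g, kh, kw)
        if need_dx:
            dcols = dyg @ wg[g].reshape(cog, -1)
            dxs.append(col2im(dcols, (n, c_in_g, h, w), kh, kw, stride, pad))
    dx = np.concatenate(dxs, axis=1) if need_dx else None
    return dx, dweight.reshape(w_shape), dbias


def sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def relu(x):
    return np.maximum(x, 0.0)


class SGDMomentum:
    """Plain SGD with classical momentum over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        for k, p in self.params.items():
            v = self._v[k]
            v *= self.momentum
            v -= self.lr * grads[k]
            p += v
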