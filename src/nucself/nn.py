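"""Minimal numpy/autograd neural-network primitives.

The surrogate networks in this package are small CNNs expressed as pure
functions of nested parameter dicts, differentiated with HIPS ``autograd``.
Convolutions are written as shift-and-tensordot over the (small) kernel
support, which autograd differentiates through fast matmul vjps; bilinear
resampling is expressed as two precomputed interpolation matrices so it is
an ordinary tensordot as well.

All helpers accept plain numpy arrays (then run un-traced) or autograd
boxes; everything is float32.
"""

from __future__ import annotations

from functools import lru_cache

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive

__all__ = [
    "conv2d", "relu", "sigmoid", "linear", "upsample_bilinear",
    "bilinear_sample", "l2_normalize", "conv_init", "dense_init",
    "tree_map", "tree_flatten_values", "AdamW",
]


def relu(x):
    return anp.maximum(x, 0.0)


@primitive
def sigmoid(x):
    # tanh form is numerically stable on both tails
    return 0.5 * (np.tanh(0.5 * np.asarray(x)) + 1.0)


defvjp(sigmoid, lambda ans, x: lambda g: g * ans * (1.0 - ans))


def _windows(x, kh, kw, stride):
    """Zero-pad to 'same' and expose (kh, kw) sliding windows as a view:
    (..., C, Ho, Wo, kh, kw)."""
    ph, pw = kh // 2, kw // 2
    pad = ((0, 0),) * (x.ndim - 2) + ((ph, ph), (pw, pw))
    xp = np.pad(x, pad, mode="constant")
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(-2, -1))
    return win[..., ::stride, ::stride, :, :]


@primitive
def _conv2d_raw(x, W, stride=1):
    """Channel-first 'same' convolution; x: (C,H,W) or (B,C,H,W),
    W: (Cout,Cin,kh,kw). A single autograd primitive with hand-written
    vjps — far cheaper than tracing per-slice operations."""
    win = _windows(x, W.shape[2], W.shape[3], stride)
    if x.ndim == 4:
        return np.einsum("ocij,bchwij->bohw", W, win, optimize=True)
    return np.einsum("ocij,chwij->ohw", W, win, optimize=True)


def _conv2d_vjp_x(ans, x, W, stride=1):
    kh, kw = W.shape[2], W.shape[3]
    ph, pw = kh // 2, kw // 2
    H, Wd = x.shape[-2], x.shape[-1]

    def vjp(g):
        gx = np.zeros(x.shape[:-2] + (H + 2 * ph, Wd + 2 * pw), dtype=x.dtype)
        ch_axis = 1 if x.ndim == 4 else 0
        for i in range(kh):
            for j in range(kw):
                t = np.tensordot(W[:, :, i, j], g, axes=[[0], [ch_axis]])
                if x.ndim == 4:
                    t = np.moveaxis(t, 1, 0)
                gx[..., i:i + H:stride, j:j + Wd:stride] += t
        return gx[..., ph:ph + H, pw:pw + Wd]

    return vjp


def _conv2d_vjp_W(ans, x, W, stride=1):
    kh, kw = W.shape[2], W.shape[3]

    def vjp(g):
        win = _windows(x, kh, kw, stride)
        if x.ndim == 4:
            return np.einsum("bohw,bchwij->ocij", g, win, optimize=True)
        return np.einsum("ohw,chwij->ocij", g, win, optimize=True)

    return vjp


defvjp(_conv2d_raw, _conv2d_vjp_x, _conv2d_vjp_W)


def conv2d(x, W, b=None, stride=1):
    """2-D convolution with 'same' zero padding.

    x: (..., C_in, H, W) with at most one leading batch axis;
    W: (C_out, C_in, kh, kw); output (..., C_out, ceil(H/stride), ceil(W/stride)).
    """
    out = _conv2d_raw(x, W, stride)
    if b is not None:
        out = out + b.reshape((-1, 1, 1))
    return out


def linear(x, W, b=None):
    """x: (..., d_in); W: (d_in, d_out)."""
    y = anp.tensordot(x, W, axes=[[-1], [0]])
    if b is not None:
        y = y + b
    return y


@lru_cache(maxsize=32)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) bilinear interpolation matrix, half-pixel aligned."""
    scale = n_in / n_out
    pos = (np.arange(n_out) + 0.5) * scale - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w_hi = pos - lo
    M = np.zeros((n_out, n_in), dtype=np.float32)
    M[np.arange(n_out), lo] += 1.0 - w_hi
    M[np.arange(n_out), hi] += w_hi
    return M


def upsample_bilinear(x, out_hw):
    """Bilinearly resample the last two axes of x to ``out_hw``."""
    Hb, Wb = out_hw
    Uh = _interp_matrix(x.shape[-2], Hb)
    Uw = _interp_matrix(x.shape[-1], Wb)
    y = anp.tensordot(x, Uw, axes=[[-1], [1]])       # (..., h, W_out)
    y = anp.tensordot(y, Uh, axes=[[-2], [1]])       # (..., W_out, H_out)
    return anp.swapaxes(y, -1, -2)


def bilinear_sample(feat, coords):
    """Sample (C, h, w) features at fractional (row, col) coords, (N, 2).

    Returns (N, C). Coordinates are clamped to the valid range; gradients
    flow into ``feat``.
    """
    h, w = feat.shape[-2], feat.shape[-1]
    r = np.clip(np.asarray(coords, dtype=np.float64)[:, 0], 0, h - 1)
    c = np.clip(np.asarray(coords, dtype=np.float64)[:, 1], 0, w - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    wr = (r - r0).astype(np.float32)[:, None]
    wc = (c - c0).astype(np.float32)[:, None]
    f00 = anp.swapaxes(feat[:, r0, c0], 0, 1)
    f01 = anp.swapaxes(feat[:, r0, c1], 0, 1)
    f10 = anp.swapaxes(feat[:, r1, c0], 0, 1)
    f11 = anp.swapaxes(feat[:, r1, c1], 0, 1)
    return ((1 - wr) * (1 - wc) * f00 + (1 - wr) * wc * f01
            + wr * (1 - wc) * f10 + wr * wc * f11)


def l2_normalize(x, axis=-1, eps=1e-12):
    return x / anp.sqrt(anp.sum(x * x, axis=axis, keepdims=True) + eps)


def conv_init(rng, c_out, c_in, k, zero=False, scale=1.0):
    if zero:
        return np.zeros((c_out, c_in, k, k), dtype=np.float32)
    std = scale * np.sqrt(2.0 / (c_in * k * k))
    return (rng.standard_normal((c_out, c_in, k, k)) * std).astype(np.float32)


def dense_init(rng, d_in, d_out, zero=False):
    if zero:
        return np.zeros((d_in, d_out), dtype=np.float32)
    std = np.sqrt(2.0 / d_in)
    return (rng.standard_normal((d_in, d_out)) * std).astype(np.float32)


def tree_map(f, tree):
    if isinstance(tree, dict):
        return {k: tree_map(f, v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return type(tree)(tree_map(f, v) for v in tree)
    return f(tree)


def tree_map2(f, a, b):
    if isinstance(a, dict):
        return {k: tree_map2(f, a[k], b[k]) for k in a}
    if isinstance(a, (list, tuple)):
        return type(a)(tree_map2(f, x, y) for x, y in zip(a, b))
    return f(a, b)


def tree_flatten_values(tree, prefix=""):
    """Flatten a nested dict/list of arrays into {'dotted.path': array}."""
    out = {}
    if isinstance(tree, dict):
        for k, v in tree.items():
            out.update(tree_flatten_values(v, f"{prefix}{k}."))
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            out.update(tree_flatten_values(v, f"{prefix}{i}."))
    else:
        out[prefix[:-1]] = tree
    return out


class AdamW:
    """AdamW over a parameter pytree (decoupled weight decay)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = tree_map(np.zeros_like, params)
        self.v = tree_map(np.zeros_like, params)

    def step(self, params, grads, lr=None, lr_map=None):
        """One update. ``lr_map`` optionally assigns a learning rate per
        top-level parameter group (falling back to ``lr``)."""
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        self.m = tree_map2(lambda m, g: b1 * m + (1 - b1) * g, self.m, grads)
        self.v = tree_map2(lambda v, g: b2 * v + (1 - b2) * g * g, self.v, grads)

        def upd(rate):
            def f(p, mv):
                m, v = mv
                step = rate * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                return (p - step - rate * self.wd * p).astype(np.float32)
            return f

        zipped = tree_map2(lambda m, v: (m, v), self.m, self.v)
        if lr_map is None or not isinstance(params, dict):
            return tree_map2(upd(lr), params, zipped)
        return {k: tree_map2(upd(lr_map.get(k, lr)), params[k], zipped[k])
                for k in params}


def cosine_annealing_lr(lr0: float, t: int, t_max: int, eta_min: float = 0.0) -> float:
    """Cosine-annealed learning rate with period ``t_max`` epochs."""
    return eta_min + 0.5 * (lr0 - eta_min) * (1 + np.cos(np.pi * (t % (2 * t_max)) / t_max))
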