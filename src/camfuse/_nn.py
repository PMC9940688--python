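"""Minimal numpy building blocks for the tiny backbones and the fusion network.

Everything here is forward-only: the pipeline needs gradients of a class
score with respect to the CAM target-layer activations, and every model in
this package places only a global-average-pool + linear head *after* that
layer, so the gradient is analytic (see ``backbones``). Layers take
parameters explicitly so models can store them in a flat, name-keyed dict.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "he_normal",
    "glorot_uniform",
    "conv2d",
    "relu",
    "gelu",
    "softmax",
    "layer_norm",
    "linear",
    "multi_head_attention",
]


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None, stride: int = 1) -> np.ndarray:
    """2-D convolution (cross-correlation) with zero 'same' padding.

    x: (C_in, H, W); w: (C_out, C_in, kh, kw); returns (C_out, ceil(H/s), ceil(W/s)).
    """
    cout, cin, kh, kw = w.shape
    if x.shape[0] != cin:
        raise ValueError(f"conv2d: input has {x.shape[0]} channels, kernel expects {cin}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (C_in, H, W, kh, kw)
    win = win[:, ::stride, ::stride]
    out = np.einsum("cijkl,ockl->oij", win, w, optimize=True)
    if b is not None:
        out += b[:, None, None]
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def gelu(x: np.ndarray) -> np.ndarray:
    # tanh approximation, adequate for forward-only tiny models
    return 0.5 * x * (1.0 + np.tanh(np.sqrt(2.0 / np.pi) * (x + 0.044715 * x**3)))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def linear(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    out = x @ w
    if b is not None:
        out = out + b
    return out


def multi_head_attention(
    x: np.ndarray,
    w_qkv: np.ndarray,
    b_qkv: np.ndarray,
    w_proj: np.ndarray,
    b_proj: np.ndarray,
    n_heads: int,
) -> np.ndarray:
    """Standard self-attention over a token sequence x of shape (T, D)."""
    t, d = x.shape
    if d % n_heads:
        raise ValueError("embedding dim must be divisible by the head count")
    dh = d // n_heads
    qkv = linear(x, w_qkv, b_qkv).reshape(t, 3, n_heads, dh)
    q, k, v = qkv[:, 0], qkv[:, 1], qkv[:, 2]  # each (T, h, dh)
    att = softmax(np.einsum("thd,shd->hts", q, k) / np.sqrt(dh), axis=-1)
    out = np.einsum("hts,shd->thd", att, v).reshape(t, d)
    return linear(out, w_proj, b_proj)
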