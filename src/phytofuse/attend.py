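"""Attention mechanisms.

The central operator is *embedding attention*: scaled dot-product
self-attention applied jointly over the concatenated image-derived and
sensor-derived tokens, so weights are allocated across both modalities at
once.  Ablation baselines: per-modality (image-only) self-attention,
channel attention, spatial attention, and CBAM (channel then spatial).

The functional :func:`embedding_attention` follows the bare definition
(per layer: softmax(Q K^T / sqrt(d)) V added residually); the trainable
:class:`EmbeddingAttentionStack` additionally layer-normalizes after each
residual, an implementation choice needed for stable training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .nn import Tensor, Module, Linear, LayerNorm, Conv2d, as_tensor, softmax, conv2d


@dataclass
class AttentionLayer:
    """Parameter container for one attention layer."""
    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    scale: Optional[float] = None  # defaults to sqrt(D)

    def __post_init__(self):
        d = self.wq.shape[0]
        if self.scale is None:
            self.scale = float(np.sqrt(d))
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def random(cls, dim: int, rng: np.random.Generator) -> "AttentionLayer":
        s = 1.0 / np.sqrt(dim)
        return cls(wq=rng.normal(0, s, (dim, dim)),
                   wk=rng.normal(0, s, (dim, dim)),
                   wv=rng.normal(0, s, (dim, dim)))


def attention_weights(tokens: np.ndarray, layer: AttentionLayer) -> np.ndarray:
    """The N x N softmax weight matrix of one layer (rows sum to 1)."""
    q = tokens @ layer.wq.T
    k = tokens @ layer.wk.T
    scores = q @ k.T / layer.scale
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=-1, keepdims=True)


def embedding_attention(tokens: np.ndarray,
                        layers: Sequence[AttentionLayer]) -> np.ndarray:
    """Apply a stack of attention layers over an N x D token set.

    Per layer: Q = Wq F, K = Wk F, V = Wv F; output =
    softmax(Q K^T / scale) V + F (residual).  The token set is expected to
    be the concatenation of image-derived and sensor-derived tokens so that
    attention spans both modalities jointly.
    """
    x = np.asarray(tokens, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("tokens must be an N x D array with N >= 1")
    if not np.isfinite(x).all():
        raise FloatingPointError("non-finite token values")
    for layer in layers:
        a = attention_weights(x, layer)
        v = x @ layer.wv.T
        x = a @ v + x
    return x


class EmbeddingAttentionStack(Module):
    """Trainable attention stack (adds layer norm after each residual)."""

    def __init__(self, dim: int, n_layers: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.qs = [Linear(dim, dim, rng, bias=False) for _ in range(n_layers)]
        self.ks = [Linear(dim, dim, rng, bias=False) for _ in range(n_layers)]
        self.vs = [Linear(dim, dim, rng, bias=False) for _ in range(n_layers)]
        self.lns = [LayerNorm(dim) for _ in range(n_layers)]
        self.scale = float(np.sqrt(dim))

    def forward(self, x: Tensor) -> Tensor:
        """(B, N, D) -> (B, N, D)."""
        for wq, wk, wv, ln in zip(self.qs, self.ks, self.vs, self.lns):
            q, k, v = wq(x), wk(x), wv(x)
            a = softmax(q @ k.swapaxes(-1, -2) * (1.0 / self.scale), axis=-1)
            x = ln(x + a @ v)
        return x


class ChannelAttention(Module):
    """Squeeze-and-excite style gating: z_c = spatial mean of channel c,
    s = sigmoid(FC2(relu(FC1(z)))), output channel c = s_c * channel c."""

    def __init__(self, channels: int, reduction: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, H, W) -> (B, C, H, W)."""
        z = x.mean(axis=(2, 3))                       # (B, C)
        s = self.fc2(self.fc1(z).relu()).sigmoid()    # (B, C)
        b, c = s.shape
        return x * s.reshape(b, c, 1, 1)

    def pooled(self, fmap: np.ndarray) -> np.ndarray:
        """z vector for a single channels-last H x W x C map."""
        return np.asarray(fmap, dtype=float).mean(axis=(0, 1))

    def apply_numpy(self, fmap: np.ndarray) -> np.ndarray:
        """Single channels-last H x W x C map in, same shape out."""
        x = Tensor(np.asarray(fmap, dtype=float).transpose(2, 0, 1)[None])
        return self.forward(x).data[0].transpose(1, 2, 0)


class SpatialAttention(Module):
    """Channel-wise mean and max maps stacked, 7x7 conv (padded), sigmoid,
    multiplied position-wise into the input."""

    def __init__(self, kernel: int = 7, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv = Conv2d(2, 1, kernel, rng, stride=1, padding=kernel // 2)

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, H, W) -> (B, C, H, W)."""
        avg = x.mean(axis=1, keepdims=True)
        # channel max is a gather; route gradients through the argmax indices
        idx = np.argmax(x.data, axis=1, keepdims=True)
        b, _, h, w = x.shape
        bi = np.arange(b)[:, None, None, None]
        hi = np.arange(h)[None, None, :, None]
        wi = np.arange(w)[None, None, None, :]
        mx = x[bi, idx, hi, wi]
        from .nn import concatenate
        gate = self.conv(concatenate([avg, mx], axis=1)).sigmoid()
        return x * gate

    def apply_numpy(self, fmap: np.ndarray) -> np.ndarray:
        x = Tensor(np.asarray(fmap, dtype=float).transpose(2, 0, 1)[None])
        return self.forward(x).data[0].transpose(1, 2, 0)


class CBAM(Module):
    """Convolutional Block Attention Module: channel gating then spatial."""

    def __init__(self, channels: int, reduction: int = 4, kernel: int = 7,
                 seed: int = 0):
        self.channel = ChannelAttention(channels, reduction, seed=seed)
        self.spatial = SpatialAttention(kernel, seed=seed + 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))

    def apply_numpy(self, fmap: np.ndarray) -> np.ndarray:
        x = Tensor(np.asarray(fmap, dtype=float).transpose(2, 0, 1)[None])
        return self.forward(x).data[0].transpose(1, 2, 0)


def channel_attention(fmap: np.ndarray, module: Optional[ChannelAttention] = None,
                      seed: int = 0) -> np.ndarray:
    """Functional convenience for a single channels-last H x W x C map."""
    if module is None:
        module = ChannelAttention(fmap.shape[-1], seed=seed)
    return module.apply_numpy(fmap)


def spatial_attention(fmap: np.ndarray, module: Optional[SpatialAttention] = None,
                      seed: int = 0) -> np.ndarray:
    if module is None:
        module = SpatialAttention(seed=seed)
    return module.apply_numpy(fmap)


def cbam(fmap: np.ndarray, module: Optional[CBAM] = None,
         seed: int = 0) -> np.ndarray:
    if module is None:
        module = CBAM(fmap.shape[-1], seed=seed)
    return module.apply_numpy(fmap)
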