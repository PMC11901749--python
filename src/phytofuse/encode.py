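"""Modality encoders.

Image pathway: a small convolutional backbone producing a spatial feature
map Fv (channels-last in the public type).  Sensor pathway: hourly channel
streams are averaged into equal time bins, standardized with training-set
statistics, turned into per-(channel, bin) tokens with channel and bin
encodings, and passed through a small transformer-style self-attention
encoder producing token features Ft.

The "resnet50" backbone option is declared for fidelity with large-scale
runs but requires pretrained weights that cannot be bundled here; selecting
it raises an informative error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .nn import Tensor, Module, Linear, Conv2d, LayerNorm, softmax
from .syndata import CHANNELS, LabeledImage, SensorWindow


@dataclass
class ImageFeature:
    map: np.ndarray      # Hv x Wv x Cv
    pooled: np.ndarray   # Cv (spatial mean)

    def __post_init__(self):
        if self.map.ndim != 3 or min(self.map.shape[:2]) < 1:
            raise ValueError("feature map must be Hv x Wv x Cv with Hv, Wv >= 1")
        if not np.isfinite(self.map).all():
            raise ValueError("non-finite values in feature map")


@dataclass
class SensorFeature:
    tokens: np.ndarray   # N_t x Ct
    pooled: np.ndarray   # Ct

    def __post_init__(self):
        if not np.isfinite(self.tokens).all():
            raise ValueError("non-finite values in sensor tokens")


class TinyCNN(Module):
    """Three stride-2 conv blocks; 64x64 input -> 8x8 feature map."""

    MIN_INPUT = 8

    def __init__(self, out_channels: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(3, 16, 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(16, 32, 3, rng, stride=2, padding=1)
        self.conv3 = Conv2d(32, out_channels, 3, rng, stride=2, padding=1)
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, 3, H, W) -> (B, Cv, H/8, W/8)."""
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        return self.conv3(x).relu()


class EncoderLayer(Module):
    """Single-head self-attention + FFN, both with residuals and layer norm."""

    def __init__(self, dim: int, rng: np.random.Generator, ffn_mult: int = 2):
        self.wq = Linear(dim, dim, rng, bias=False)
        self.wk = Linear(dim, dim, rng, bias=False)
        self.wv = Linear(dim, dim, rng, bias=False)
        self.ln1 = LayerNorm(dim)
        self.ffn1 = Linear(dim, ffn_mult * dim, rng)
        self.ffn2 = Linear(ffn_mult * dim, dim, rng)
        self.ln2 = LayerNorm(dim)
        self.scale = float(np.sqrt(dim))

    def forward(self, x: Tensor) -> Tensor:
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        att = softmax(q @ k.swapaxes(-1, -2) * (1.0 / self.scale), axis=-1)
        x = self.ln1(x + att @ v)
        return self.ln2(x + self.ffn2(self.ffn1(x).relu()))


class SensorEncoder(Module):
    """Transformer-style encoder over binned, standardized channel tokens."""

    def __init__(self, bins: int = 6, layers: int = 2, dim: int = 32,
                 n_channels: int = len(CHANNELS), seed: int = 0):
        if bins < 1 or layers < 0 or dim < 1:
            raise ValueError("bins >= 1, layers >= 0, dim >= 1 required")
        rng = np.random.default_rng(seed)
        self.bins = bins
        self.dim = dim
        self.n_channels = n_channels
        self.value_w = Tensor(rng.normal(0, 1.0, size=dim), requires_grad=True)
        self.value_b = Tensor(np.zeros(dim), requires_grad=True)
        self.channel_emb = Tensor(rng.normal(0, 0.5, size=(n_channels, dim)),
                                  requires_grad=True)
        self.bin_emb = Tensor(rng.normal(0, 0.5, size=(bins, dim)),
                              requires_grad=True)
        self.layers = [EncoderLayer(dim, rng) for _ in range(layers)]
        # standardization statistics (training-set only; see fit_standardizer)
        self._mu: Optional[np.ndarray] = None
        self._sd: Optional[np.ndarray] = None

    # -------------------------------------------------------- preprocessing
    def bin_readings(self, readings: np.ndarray) -> np.ndarray:
        """(..., C, T) -> (..., C, bins) by equal-bin averaging; T is padded
        with its final value when not divisible by `bins`."""
        t = readings.shape[-1]
        if t < 1:
            raise ValueError("empty sensor window")
        rem = (-t) % self.bins
        if rem:
            pad = np.repeat(readings[..., -1:], rem, axis=-1)
            readings = np.concatenate([readings, pad], axis=-1)
        t2 = readings.shape[-1]
        shaped = readings.reshape(*readings.shape[:-1], self.bins, t2 // self.bins)
        return shaped.mean(axis=-1)

    def fit_standardizer(self, windows: Sequence[SensorWindow]) -> None:
        """Compute per-channel mean/sd of binned values on the training set."""
        binned = np.stack([self.bin_readings(w.readings) for w in windows])
        self._mu = binned.mean(axis=(0, 2))
        self._sd = binned.std(axis=(0, 2))
        self._sd = np.where(self._sd < 1e-8, 1.0, self._sd)

    @property
    def standardizer(self):
        return self._mu, self._sd

    def set_standardizer(self, mu: np.ndarray, sd: np.ndarray) -> None:
        self._mu = np.asarray(mu, dtype=float)
        self._sd = np.asarray(sd, dtype=float)

    # -------------------------------------------------------------- forward
    def tokens(self, readings: np.ndarray) -> Tensor:
        """(B, C, T) raw readings -> (B, C*bins, dim) token embeddings."""
        if self._mu is None:
            raise RuntimeError("standardizer not fitted; call fit_standardizer "
                               "on the training split first")
        binned = self.bin_readings(readings)                       # (B, C, bins)
        z = (binned - self._mu[None, :, None]) / self._sd[None, :, None]
        zt = Tensor(z[..., None])                                  # (B, C, bins, 1)
        tok = zt * self.value_w + self.value_b
        tok = tok + self.channel_emb.reshape(1, self.n_channels, 1, self.dim)
        tok = tok + self.bin_emb.reshape(1, 1, self.bins, self.dim)
        b = readings.shape[0]
        return tok.reshape(b, self.n_channels * self.bins, self.dim)

    def forward(self, readings: np.ndarray) -> Tensor:
        """(B, C, T) -> (B, N_t, dim) encoded tokens."""
        x = self.tokens(readings)
        for layer in self.layers:
            x = layer(x)
        return x


# ------------------------------------------------------- functional wrappers

def encode_image(img: LabeledImage,
                 backbone: Union[str, TinyCNN] = "tinycnn") -> ImageFeature:
    """Run one image through the backbone (inference only)."""
    if isinstance(backbone, str):
        if backbone == "tinycnn":
            backbone = TinyCNN()
        elif backbone == "resnet50":
            raise NotImplementedError(
                "resnet50 requires pretrained weights that are not bundled; "
                "use backbone='tinycnn'")
        else:
            raise ValueError(f"unknown backbone {backbone!r}")
    h, w = img.pixels.shape[:2]
    if min(h, w) < TinyCNN.MIN_INPUT:
        raise ValueError(f"image {h}x{w} below backbone minimum "
                         f"{TinyCNN.MIN_INPUT}")
    x = Tensor(img.pixels.astype(np.float64).transpose(2, 0, 1)[None] / 255.0)
    fmap = backbone(x).data[0]                     # (Cv, Hv, Wv)
    fmap = fmap.transpose(1, 2, 0)                 # channels-last
    return ImageFeature(map=fmap, pooled=fmap.mean(axis=(0, 1)))


def encode_sensors(w: SensorWindow, bins: int = 6, layers: int = 2,
                   dim: int = 32,
                   encoder: Optional[SensorEncoder] = None) -> SensorFeature:
    """Encode one window.  If no fitted encoder is supplied, a fresh one is
    built and its standardizer fitted on this window alone (useful for
    inspection; training fits on the training split)."""
    if w.readings.size == 0:
        raise ValueError("empty sensor window")
    if encoder is None:
        encoder = SensorEncoder(bins=bins, layers=layers, dim=dim,
                                n_channels=len(w.channel_names))
    if encoder.standardizer[0] is None:
        encoder.fit_standardizer([w])
    toks = encoder(w.readings[None]).data[0]
    return SensorFeature(tokens=toks, pooled=toks.mean(axis=0))
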