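"""Fusion of image and sensor features.

Four selectable modes:

* ``weighted_sum``:     Fm = alpha * Fv + (1 - alpha) * Ft
* ``weighted_concat``:  Fm = [alpha * Fv ; (1 - alpha) * Ft]   (default)
* ``concat``:           Fm = [Fv ; Ft]
* ``bilinear``:         Fm = softmax(Fv . W . Ft) . Fv, the softmax taken
  over the image token axis (the only axis that keeps the product
  shape-consistent).

Plus the post-fusion projection Fm' = ReLU(Wf Fm + bf) and a histogram-KL
diagnostic of the divergence between the two modalities' pooled-feature-norm
distributions (logged, never trained on).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .nn import Tensor, Module, Linear, as_tensor, concatenate, softmax

logger = logging.getLogger(__name__)

FUSION_MODES = ("weighted_sum", "weighted_concat", "concat", "bilinear")


@dataclass
class FusedFeature:
    fm: np.ndarray
    fm_prime: Optional[np.ndarray]
    alpha: float
    mode: str


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def fuse(fv: Union[np.ndarray, Tensor], ft: Union[np.ndarray, Tensor],
         mode: str = "weighted_concat", alpha: Union[float, Tensor] = 0.5,
         bilinear_w: Optional[Union[np.ndarray, Tensor]] = None
         ) -> Union[np.ndarray, Tensor]:
    """Fuse projected modality features (works on single vectors or batches;
    for ``bilinear``, `fv` carries image tokens (..., N_v, D) and `ft` a
    pooled vector (..., D))."""
    if mode not in FUSION_MODES:
        raise ValueError(f"unknown fusion mode {mode!r}")
    tensor_mode = isinstance(fv, Tensor) or isinstance(ft, Tensor) \
        or isinstance(alpha, Tensor)
    a, b = as_tensor(fv), as_tensor(ft)
    if mode == "bilinear":
        if bilinear_w is None:
            raise ValueError("bilinear mode requires the weight matrix W")
        w = as_tensor(bilinear_w)
        scores = a @ w @ b.reshape(*b.shape, 1)          # (..., N_v, 1)
        att = softmax(scores.reshape(*scores.shape[:-1]), axis=-1)
        out = att.reshape(*att.shape, 1).swapaxes(-1, -2) @ a
        out = out.reshape(*out.shape[:-2], out.shape[-1])
        return out if tensor_mode else out.data
    if mode != "concat":
        if a.shape[-1] != b.shape[-1] and mode == "weighted_sum":
            raise ValueError(
                f"weighted_sum needs equal dims: image {a.shape[-1]} vs "
                f"sensor {b.shape[-1]}")
        a = a * alpha
        b = b * (1.0 - alpha) if isinstance(alpha, Tensor) else b * (1.0 - float(alpha))
    if mode == "weighted_sum":
        out = a + b
    else:
        out = concatenate([a, b], axis=-1)
    return out if tensor_mode else out.data


class FusionModule(Module):
    """Trainable fusion: alpha = sigmoid(raw) so alpha is in (0, 1) by
    construction; bilinear carries a learnable D x D weight."""

    def __init__(self, dim: int, mode: str = "weighted_concat",
                 alpha_init: float = 0.5, seed: int = 0):
        if mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {mode!r}")
        if not (0.0 < alpha_init < 1.0):
            raise ValueError("alpha_init must be in (0, 1)")
        rng = np.random.default_rng(seed)
        self.mode = mode
        self.dim = dim
        raw0 = float(np.log(alpha_init / (1.0 - alpha_init)))
        self.alpha_raw = Tensor(np.array(raw0), requires_grad=True)
        self.bilinear_w = (Tensor(rng.normal(0, 1 / np.sqrt(dim), (dim, dim)),
                                  requires_grad=True)
                           if mode == "bilinear" else None)

    @property
    def alpha(self) -> float:
        return _sigmoid(float(self.alpha_raw.data))

    @property
    def out_dim(self) -> int:
        return 2 * self.dim if self.mode in ("weighted_concat", "concat") \
            else self.dim

    def forward(self, fv: Tensor, ft: Tensor) -> Tensor:
        alpha_t = self.alpha_raw.sigmoid()
        return fuse(fv, ft, mode=self.mode, alpha=alpha_t,
                    bilinear_w=self.bilinear_w)


def project_and_head(fm: Union[np.ndarray, Tensor],
                     wf: Union[np.ndarray, Tensor],
                     bf: Union[np.ndarray, Tensor]) -> Union[np.ndarray, Tensor]:
    """Fm' = ReLU(Wf Fm + bf); Wf is (D_o, D_m), applied as Wf @ fm."""
    tensor_mode = isinstance(fm, Tensor)
    f, w, b = as_tensor(fm), as_tensor(wf), as_tensor(bf)
    if w.shape[-1] != f.shape[-1]:
        raise ValueError(f"Wf columns {w.shape[-1]} != feature dim {f.shape[-1]}")
    out = (f @ w.swapaxes(-1, -2) + b).relu()
    return out if tensor_mode else out.data


def modality_divergence(fv_batch: np.ndarray, ft_batch: np.ndarray,
                        bins: int = 10) -> Optional[float]:
    """KL divergence between histogram estimates (shared edges, add-one
    smoothing) of the two pooled-feature-norm distributions.  Diagnostic
    only; returns None (with a warning) below 30 samples per batch."""
    fv_batch, ft_batch = np.asarray(fv_batch), np.asarray(ft_batch)
    if len(fv_batch) < 30 or len(ft_batch) < 30:
        logger.warning("modality_divergence skipped: need >= 30 samples per "
                       "batch (got %d, %d)", len(fv_batch), len(ft_batch))
        return None
    nv = np.linalg.norm(fv_batch, axis=-1)
    nt = np.linalg.norm(ft_batch, axis=-1)
    lo = min(nv.min(), nt.min())
    hi = max(nv.max(), nt.max())
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(nv, bins=edges)[0] + 1.0
    q = np.histogram(nt, bins=edges)[0] + 1.0
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))
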