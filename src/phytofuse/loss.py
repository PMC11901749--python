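"""Classification and alignment objectives.

Cross-entropy (soft-label capable), focal loss, cosine alignment loss, and
the composite embedding loss  L = L_CE + lambda * L_align, with optional
per-class weighting.  All functions accept either numpy arrays (returning
floats) or autodiff Tensors (returning Tensors, so gradients flow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .nn import Tensor, as_tensor, clip_min

logger = logging.getLogger(__name__)

ArrayOrTensor = Union[np.ndarray, Tensor]

_PROB_EPS = 1e-12
_NORM_EPS = 1e-8


@dataclass
class LossConfig:
    kind: str = "embedding"  # "ce" | "focal" | "embedding"
    lambda_align: float = 0.5
    focal_gamma: float = 2.0
    focal_alpha: float = 1.0
    class_weights: Union[str, np.ndarray, None] = None  # None | "inverse_frequency" | vector

    def __post_init__(self):
        if self.kind not in ("ce", "focal", "embedding"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.lambda_align < 0:
            raise ValueError("lambda_align must be >= 0")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not (0 < self.focal_alpha <= 1):
            raise ValueError("focal_alpha must be in (0, 1]")


@dataclass
class LossBreakdown:
    ce: float
    align: float
    total: float
    n: int


def _ret(x: Tensor, tensor_mode: bool):
    return x if tensor_mode else float(x.data)


def _validate_probs(probs: np.ndarray) -> None:
    sums = probs.sum(axis=-1)
    if np.abs(sums - 1.0).max() > 1e-6:
        worst = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"probability row {worst} sums to {sums.flat[worst]:.8f}, not 1")


def inverse_frequency_weights(labels: np.ndarray) -> np.ndarray:
    """Per-class weights w_c proportional to 1/n_c, normalised so that
    sum_c w_c * n_c = N (classes absent from `labels` get weight 0)."""
    y = np.asarray(labels, dtype=float)
    counts = y.sum(axis=0)
    present = counts > 0
    k = int(present.sum())
    w = np.zeros_like(counts)
    w[present] = y.shape[0] / (k * counts[present])  # => sum_c w_c n_c = N
    return w


def _resolve_weights(weights, labels_np: np.ndarray) -> Optional[np.ndarray]:
    if weights is None:
        return None
    if isinstance(weights, str):
        if weights != "inverse_frequency":
            raise ValueError(f"unknown weight spec {weights!r}")
        return inverse_frequency_weights(labels_np)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("class weights must be positive")
    return w


def cross_entropy(probs: ArrayOrTensor, labels: ArrayOrTensor,
                  weights=None) -> Union[float, Tensor]:
    """L = -(1/N) sum_i sum_c w_c * y_ic * log(p_ic). Supports soft labels."""
    tensor_mode = isinstance(probs, Tensor)
    p, y = as_tensor(probs), as_tensor(labels)
    _validate_probs(p.data)
    w = _resolve_weights(weights, y.data)
    logp = clip_min(p, _PROB_EPS).log()
    terms = y * logp
    if w is not None:
        terms = terms * Tensor(w)
    n = p.data.shape[0]
    return _ret(-(terms.sum()) * (1.0 / n), tensor_mode)


def focal_loss(probs: ArrayOrTensor, labels: ArrayOrTensor,
               gamma: float = 2.0, alpha: float = 1.0,
               weights=None) -> Union[float, Tensor]:
    """Batch-mean multi-class focal loss:
    L = -(1/N) sum_i sum_c alpha * (1 - p_ic)^gamma * y_ic * log(p_ic).
    With gamma=0, alpha=1 this reduces exactly to cross-entropy."""
    tensor_mode = isinstance(probs, Tensor)
    p, y = as_tensor(probs), as_tensor(labels)
    _validate_probs(p.data)
    w = _resolve_weights(weights, y.data)
    pc = clip_min(p, _PROB_EPS)
    terms = y * pc.log()
    if gamma != 0:
        terms = terms * ((1.0 - p) ** float(gamma))
    if w is not None:
        terms = terms * Tensor(w)
    n = p.data.shape[0]
    return _ret(-(terms.sum()) * (float(alpha) / n), tensor_mode)


def alignment_loss(fv: ArrayOrTensor, ft: ArrayOrTensor) -> Union[float, Tensor]:
    """L = (1/N) sum_i (1 - cos(fv_i, ft_i)); range [0, 2]."""
    tensor_mode = isinstance(fv, Tensor) or isinstance(ft, Tensor)
    a, b = as_tensor(fv), as_tensor(ft)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    dot = (a * b).sum(axis=-1)
    na = ((a * a).sum(axis=-1) + _NORM_EPS ** 2) ** 0.5
    nb = ((b * b).sum(axis=-1) + _NORM_EPS ** 2) ** 0.5
    cos = dot / (na * nb)
    return _ret((1.0 - cos).mean(), tensor_mode)


def embedding_loss(probs: ArrayOrTensor, labels: ArrayOrTensor,
                   fv: ArrayOrTensor, ft: ArrayOrTensor,
                   cfg: LossConfig) -> tuple:
    """Composite objective: total = CE + lambda_align * alignment.

    Returns (total, LossBreakdown); `total` is a Tensor when inputs are
    Tensors so it can be backpropagated, and the breakdown always carries
    plain floats.
    """
    tensor_mode = isinstance(probs, Tensor)
    ce = cross_entropy(probs, labels, weights=cfg.class_weights)
    al = alignment_loss(fv, ft)
    total = ce + cfg.lambda_align * al
    ce_f = float(ce.data) if isinstance(ce, Tensor) else ce
    al_f = float(al.data) if isinstance(al, Tensor) else al
    n = (probs.data if tensor_mode else np.asarray(probs)).shape[0]
    bd = LossBreakdown(ce=ce_f, align=al_f, total=ce_f + cfg.lambda_align * al_f, n=n)
    return total, bd
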