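"""Post-training model compression: magnitude pruning and uniform weight
quantization, with before/after accuracy reporting.

Pruning keeps a weight iff |w| > epsilon (strict, so |w| == epsilon is
zeroed).  Quantization uses round-half-to-even codes w -> round(w / delta)
and dequantizes as code * delta, bounding reconstruction error by delta/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .metrics import EvalReport
from .train import TrainedModel, evaluate_model


@dataclass
class CompressionSpec:
    epsilon: float = 0.0        # pruning threshold; 0 disables (only exact zeros)
    delta: float = 1e-6         # quantization step
    scope: Optional[Sequence[str]] = None  # parameter-name prefixes; None = all

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


def prune(weights: np.ndarray, epsilon: float) -> Tuple[np.ndarray, float]:
    """W' = W * indicator(|W| > epsilon).  Returns (pruned, sparsity)."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    w = np.asarray(weights, dtype=np.float64)
    out = np.where(np.abs(w) > epsilon, w, 0.0)
    sparsity = float(np.mean(out == 0.0)) if out.size else 0.0
    return out, sparsity


def quantize(weights: np.ndarray, delta: float) -> Tuple[np.ndarray, np.ndarray]:
    """codes = round(W / delta) (half-to-even); returns (codes, codes*delta)."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    w = np.asarray(weights, dtype=np.float64)
    codes = np.rint(w / delta)  # numpy rint rounds half to even
    return codes.astype(np.int64), codes * delta


def compress_model(model: TrainedModel, spec: CompressionSpec) -> Dict[str, float]:
    """Prune then quantize the model's parameters in place (within scope).
    Returns summary stats (sparsity, max reconstruction error, bits)."""
    state = model.net.state_dict()
    n_total = n_zero = 0
    max_err = 0.0
    max_code = 0
    new_state = {}
    for name, w in state.items():
        if spec.scope is not None and not any(name.startswith(s)
                                              for s in spec.scope):
            new_state[name] = w
            continue
        pruned, _ = prune(w, spec.epsilon)
        codes, deq = quantize(pruned, spec.delta)
        max_err = max(max_err, float(np.max(np.abs(pruned - deq), initial=0.0)))
        max_code = max(max_code, int(np.max(np.abs(codes), initial=0)))
        n_total += deq.size
        n_zero += int(np.sum(deq == 0.0))
        new_state[name] = deq
    model.net.load_state_dict(new_state)
    bits = int(np.ceil(np.log2(2 * max_code + 1))) if max_code else 1
    return {"sparsity": n_zero / max(n_total, 1),
            "max_reconstruction_error": max_err,
            "bits_per_weight": bits,
            "code_size_bytes": int(np.ceil(n_total * bits / 8))}


def report_compression(model: TrainedModel, spec: CompressionSpec,
                       eval_samples) -> Dict:
    """Evaluate before and after compressing; report metric deltas and size."""
    before = evaluate_model(model, eval_samples)
    stats = compress_model(model, spec)
    after = evaluate_model(model, eval_samples)
    deltas = {k: after.macro[k] - before.macro[k]
              for k in before.macro if k in after.macro}
    return {"before": before, "after": after, "deltas": deltas, **stats}
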