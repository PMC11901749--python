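"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .tensor import Tensor


class Adam:
    """Adam with L2 weight decay added to the gradient (classic coupling)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """eta_t = 0.5 * (1 + cos(pi * t / T)) * eta_0."""
    if total_epochs <= 0:
        return lr0
    return 0.5 * (1.0 + math.cos(math.pi * epoch / total_epochs)) * lr0
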