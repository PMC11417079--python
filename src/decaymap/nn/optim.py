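"""Decoupled-weight-decay adaptive gradient optimizer (AdamW)."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["AdamW"]


class AdamW:
    """AdamW: Adam moments plus weight decay applied directly to weights."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 0.002,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = [p for p in params if p.trainable]
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
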