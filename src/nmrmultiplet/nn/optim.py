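"""Adam optimizer with global-norm gradient clipping."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(
        self,
        model,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        clip_norm: float | None = 5.0,
    ):
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p in model.parameters()}
        self.v = {k: np.zeros_like(p) for k, p in model.parameters()}

    def step(self) -> None:
        grads = dict(self.model.gradients())
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for key, p in self.model.parameters():
            g = grads[key]
            m = self.m[key]
            v = self.v[key]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
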