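"""Optimizers for the autodiff parameters."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adaptive-moment gradient descent (the standard bias-corrected form)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self._m], "v": [v.copy() for v in self._v]}

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self._m = [np.asarray(m, dtype=np.float64) for m in state["m"]]
        self._v = [np.asarray(v, dtype=np.float64) for v in state["v"]]
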