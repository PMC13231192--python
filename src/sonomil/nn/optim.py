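"""Stochastic gradient descent with classical momentum and L2 weight decay.

Update rule (per parameter, matching the common deep-learning convention):

    buf <- momentum * buf + grad + weight_decay * param
    param <- param - lr * buf

The learning rate is passed to :meth:`SGD.step` so an external schedule can
vary it per optimisation step.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["SGD"]


class SGD:
    def __init__(self, params, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params: list[Tensor] = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data = p.data - lr * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
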