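"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["SGDMomentum"]


class SGDMomentum:
    """SGD with momentum: v <- m*v + g; p <- p - lr*v."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params = params
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
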