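"""Stochastic gradient descent with momentum and decoupled L2 weight decay."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class SGD:
    """v <- momentum * v + (grad + weight_decay * p);  p <- p - lr * v."""

    def __init__(self, params: dict[str, Tensor], lr: float = 0.02,
                 momentum: float = 0.9, weight_decay: float = 1e-4):
        self.params = dict(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.velocity = {n: np.zeros_like(p.data) for n, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        for name, p in self.params.items():
            g = p.grad
            if g is None:
                g = np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v = self.velocity[name]
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def state_dict(self):
        return {n: v.copy() for n, v in self.velocity.items()}

    def load_state_dict(self, state) -> None:
        for n in self.velocity:
            self.velocity[n] = np.asarray(state[n]).copy()
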