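"""Adam optimizer over :class:`~ramancnn.nn.core.Param` lists."""

from __future__ import annotations

import numpy as np

from .core import Param


class Adam:
    """Adam with bias correction; defaults follow the training protocol
    (learning rate 1e-4, betas (0.5, 0.999))."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
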