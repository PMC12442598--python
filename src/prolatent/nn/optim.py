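"""AdamW with decoupled weight decay and a cosine-annealed learning rate."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class CosineAnnealingLR:
    """Anneal the optimizer lr from its start value to ``eta_min`` over T_max steps."""

    def __init__(self, optimizer: AdamW, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.t_max = max(t_max, 1)
        self.eta_min = eta_min
        self.t = 0

    def step(self) -> None:
        self.t = min(self.t + 1, self.t_max)
        frac = 0.5 * (1 + math.cos(math.pi * self.t / self.t_max))
        self.optimizer.lr = self.eta_min + (self.base_lr - self.eta_min) * frac
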