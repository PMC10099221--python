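"""Stochastic gradient descent with momentum and linear warm-up."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "WarmupSchedule"]


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_grad_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.clip_grad_norm = clip_grad_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def _total_grad_norm(self) -> float:
        sq = 0.0
        for p in self.params:
            if p.grad is not None:
                sq += float((p.grad.astype(np.float64) ** 2).sum())
        return sq**0.5

    def step(self) -> None:
        scale = 1.0
        if self.clip_grad_norm is not None:
            norm = self._total_grad_norm()
            if norm > self.clip_grad_norm:
                scale = self.clip_grad_norm / (norm + 1e-12)
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data = p.data + v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class WarmupSchedule:
    """Linear warm-up from ``warmup_factor * lr`` to ``lr`` over ``warmup_iters``."""

    def __init__(self, optimizer: SGD, base_lr: float, warmup_iters: int = 500,
                 warmup_factor: float = 0.1):
        self.opt = optimizer
        self.base_lr = float(base_lr)
        self.warmup_iters = int(warmup_iters)
        self.warmup_factor = float(warmup_factor)
        self.iteration = 0
        self._apply()

    def _apply(self) -> None:
        if self.iteration < self.warmup_iters and self.warmup_iters > 0:
            alpha = self.iteration / self.warmup_iters
            f = self.warmup_factor * (1 - alpha) + alpha
        else:
            f = 1.0
        self.opt.lr = self.base_lr * f

    def step(self) -> None:
        self.iteration += 1
        self._apply()
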