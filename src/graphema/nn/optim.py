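"""Optimization utilities: Adam and percentile-based adaptive gradient
clipping (AutoClip)."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def global_grad_norm(params: list[Tensor]) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    return float(np.sqrt(total))


class AutoClip:
    """Adaptive gradient clipping at a running percentile of the observed
    gradient-norm history.

    Each step, the new global norm is appended to the (unbounded) history,
    the threshold is taken as the given percentile of that history
    (linear-interpolation convention), and gradients are rescaled when the
    current norm exceeds it. The first step is never clipped, since a
    single-element history puts every percentile at the observed norm.
    """

    def __init__(self, percentile: float = 10.0):
        if not (0.0 < percentile <= 100.0):
            raise ValueError("percentile must be in (0, 100]")
        self.percentile = percentile
        self.history: list[float] = []

    def threshold(self, new_norm: float) -> float:
        self.history.append(float(new_norm))
        return float(np.percentile(self.history, self.percentile))

    def __call__(self, params: list[Tensor]) -> float:
        norm = global_grad_norm(params)
        thr = self.threshold(norm)
        if norm > thr > 0.0:
            scale = thr / norm
            for p in params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return thr
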