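"""Optimization: AdamW with decoupled weight decay, and the triangular
cyclic learning-rate schedule used for the stenosis-assessment network."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class AdamW:
    """Adam with decoupled weight decay (weight decay applied to the value,
    not folded into the gradient moments)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.value -= (self.lr * (update + self.wd * p.value)).astype(p.value.dtype, copy=False)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def cyclic_lr(epoch: float, lr_high: float = 5e-4, lr_low: float = 1e-5,
              period: float = 40.0) -> float:
    """Triangular cyclic learning rate.

    Starts at ``lr_high``, decays linearly to ``lr_low`` at half the period,
    then rises back, repeating with the given period (in epochs). Fractional
    epochs interpolate linearly.
    """
    phase = (epoch % period) / period          # in [0, 1)
    tri = 1.0 - 2.0 * min(phase, 1.0 - phase)  # 1 at phase 0, 0 at phase .5
    return lr_low + (lr_high - lr_low) * tri
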