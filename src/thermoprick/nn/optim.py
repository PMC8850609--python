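"""Adam and AdamW (decoupled weight decay) for :class:`~thermoprick.nn.layers.Parameter`."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with optional *decoupled* weight decay (AdamW when decay > 0).

    Decay is applied multiplicatively to the weights, outside the adaptive
    gradient step, and skipped for parameters flagged ``decay=False``
    (biases, normalisation scales).
    """

    def __init__(self, params: Sequence[Parameter], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            if self.weight_decay and p.decay:
                p.value *= 1.0 - self.lr * self.weight_decay
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def AdamW(params: Sequence[Parameter], lr: float = 0.001,
          weight_decay: float = 1e-4, **kwargs) -> Adam:
    return Adam(params, lr=lr, weight_decay=weight_decay, **kwargs)
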