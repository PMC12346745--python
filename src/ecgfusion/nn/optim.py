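"""Adam optimizer over (layer, parameter-name) slots."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Layer


class Adam:
    def __init__(
        self,
        parameters: list[tuple[Layer, str]],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.slots = parameters
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[k]) for l, k in parameters]
        self.v = [np.zeros_like(l.params[k]) for l, k in parameters]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for i, (layer, k) in enumerate(self.slots):
            g = layer.grads[k].astype(np.float64)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            layer.params[k] = (
                layer.params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(DTYPE)
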