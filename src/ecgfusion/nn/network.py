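"""Network containers and the softmax cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y_onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-(y_onehot * np.log(p + eps)).sum() / n)
    dlogits = ((p - y_onehot) / n).astype(DTYPE)
    return loss, dlogits


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self.layers for k in l.params]


class DualBranchNet:
    """ECG branch (+ optional demographic branch) -> concatenation -> head.

    ``forward`` returns raw logits; probabilities come from
    :func:`softmax`. With ``demo_branch=None`` the network is ECG-only and
    the head consumes the ECG features directly.
    """

    def __init__(
        self,
        ecg_branch: Sequential,
        demo_branch: Sequential | None,
        head: Sequential,
    ) -> None:
        self.ecg_branch = ecg_branch
        self.demo_branch = demo_branch
        self.head = head
        self._ecg_dim: int | None = None

    @property
    def use_demographics(self) -> bool:
        return self.demo_branch is not None

    def forward(self, x_ecg, x_demo=None, train=False, rng=None):
        fe = self.ecg_branch.forward(x_ecg, train=train, rng=rng)
        if self.demo_branch is not None:
            if x_demo is None:
                raise ValueError("model expects demographic inputs")
            fd = self.demo_branch.forward(
                x_demo.astype(DTYPE, copy=False), train=train, rng=rng
            )
            self._ecg_dim = fe.shape[1]
            f = np.concatenate([fe, fd], axis=1)
        else:
            f = fe
        return self.head.forward(f, train=train, rng=rng)

    def backward(self, dlogits):
        df = self.head.backward(dlogits)
        if self.demo_branch is not None:
            de, dd = df[:, : self._ecg_dim], df[:, self._ecg_dim:]
            self.demo_branch.backward(dd)
            self.ecg_branch.backward(de)
        else:
            self.ecg_branch.backward(df)

    def parameters(self) -> list[tuple[Layer, str]]:
        out = self.ecg_branch.parameters()
        if self.demo_branch is not None:
            out += self.demo_branch.parameters()
        return out + self.head.parameters()

    def all_layers(self):
        layers = list(self.ecg_branch.layers)
        if self.demo_branch is not None:
            layers += self.demo_branch.layers
        return layers + list(self.head.layers)

    # --- state snapshot/restore (for best-epoch checkpointing) ---

    def get_state(self) -> list[np.ndarray]:
        state = []
        for layer in self.all_layers():
            for k in layer.params:
                state.append(layer.params[k].copy())
            if hasattr(layer, "running_mean"):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer in self.all_layers():
            for k in layer.params:
                layer.params[k] = next(it).copy()
            if hasattr(layer, "running_mean"):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    def n_parameters(self) -> int:
        return int(sum(l.params[k].size for l, k in self.parameters()))
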