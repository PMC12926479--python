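"""Optimizers (decoupled-weight-decay Adam and plain SGD)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW", "SGD"]


class AdamW:
    """Adam with decoupled weight decay.

    Decay is applied only to parameters with ndim > 1 (conv/linear weights);
    norm gains and biases are left undecayed, the usual detector practice.
    """

    def __init__(self, params, lr: float = 0.001, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0005):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay and p.data.ndim > 1:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self._m, "v": self._v}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self._m = [np.asarray(a) for a in state["m"]]
        self._v = [np.asarray(a) for a in state["v"]]


class SGD:
    def __init__(self, params, lr: float = 0.01, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            if self.momentum:
                buf *= self.momentum
                buf += p.grad
                p.data -= self.lr * buf
            else:
                p.data -= self.lr * p.grad
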