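"""Minimal first-order optimizers over lists of numpy parameter arrays."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adaptive-moment gradient descent (bias-corrected)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain (optionally momentum) gradient descent."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-2,
                 momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.buf = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, b in zip(self.params, grads, self.buf):
            if self.momentum:
                b *= self.momentum
                b += g
                g = b
            p -= self.lr * g


def make_optimizer(name: str, params: list[np.ndarray], lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr)
    if name == "momentum":
        return SGD(params, lr=lr, momentum=0.9)
    raise ValueError(f"unknown optimizer {name!r}")
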