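"""First-order optimizers over lists of Params."""

from __future__ import annotations

import numpy as np

from lvhquant.nn.layers import Param


class Optimizer:
    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr=1e-2, momentum=0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self.v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


class Adam(Optimizer):
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class Adamax(Optimizer):
    """Adam variant with an infinity-norm second moment."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.u = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        for p, m, u in zip(self.params, self.m, self.u):
            m += (1 - self.b1) * (p.grad - m)
            np.maximum(self.b2 * u, np.abs(p.grad), out=u)
            p.value -= self.lr * m / (bc1 * (u + self.eps))


class RMSprop(Optimizer):
    def __init__(self, params, lr=1e-3, rho=0.9, eps=1e-8):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self.v):
            v += (1 - self.rho) * (p.grad ** 2 - v)
            p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)


_OPTIMIZERS = {"sgd": SGD, "adam": Adam, "adamax": Adamax, "rmsprop": RMSprop}


def make_optimizer(name: str, params: list[Param], lr: float) -> Optimizer:
    key = name.lower()
    if key not in _OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}")
    return _OPTIMIZERS[key](params, lr=lr)
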