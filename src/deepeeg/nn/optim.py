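"""First-order optimizers updating parameter arrays in place."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "RMSprop", "Adadelta", "make_optimizer"]


class Optimizer:
    def __init__(self, params, grads):
        self.params = params
        self.grads = grads

    def step(self):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, grads, lr=0.01, momentum=0.0):
        super().__init__(params, grads)
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.v):
            if self.momentum:
                v *= self.momentum
                v += g
                p -= self.lr * v
            else:
                p -= self.lr * g


class Adam(Optimizer):
    def __init__(self, params, grads, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, grads, lr=1e-4, rho=0.9, eps=1e-8):
        super().__init__(params, grads)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.v):
            v *= self.rho
            v += (1.0 - self.rho) * (g * g)
            p -= self.lr * g / (np.sqrt(v) + self.eps)


class Adadelta(Optimizer):
    def __init__(self, params, grads, lr=1.0, rho=0.95, eps=1e-6):
        super().__init__(params, grads)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v, u in zip(self.params, self.grads, self.v, self.u):
            v *= self.rho
            v += (1.0 - self.rho) * (g * g)
            dx = np.sqrt(u + self.eps) / np.sqrt(v + self.eps) * g
            u *= self.rho
            u += (1.0 - self.rho) * (dx * dx)
            p -= self.lr * dx


_REGISTRY = {"sgd": SGD, "adam": Adam, "rmsprop": RMSprop, "adadelta": Adadelta}


def make_optimizer(name: str, params, grads, lr: float):
    try:
        cls = _REGISTRY[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None
    return cls(params, grads, lr=lr)
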