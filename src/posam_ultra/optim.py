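"""First-order optimizers over autograd parameters: SGD (with momentum),
Adam, and RMSprop, plus decoupled-style L2 weight decay applied as a
gradient term."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["SGD", "Adam", "RMSprop", "build_optimizer"]


class _Optimizer:
    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _grad(self, p: Tensor) -> np.ndarray:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        return g

    def step(self):
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, params, lr, momentum: float = 0.0, weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            g = self._grad(p)
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam(_Optimizer):
    def __init__(self, params, lr, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.betas = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = self._grad(p)
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, params, lr, alpha: float = 0.99, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.alpha = alpha
        self.eps = eps
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, sq in zip(self.params, self._sq):
            g = self._grad(p)
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(sq) + self.eps)


def build_optimizer(name: str, params, lr: float, weight_decay: float = 0.0,
                    momentum: float = 0.9) -> _Optimizer:
    """Construct an optimizer from its categorical name; momentum applies
    only to SGD."""
    name = name.lower()
    if name == "adam":
        return Adam(params, lr, weight_decay=weight_decay)
    if name == "sgd":
        return SGD(params, lr, momentum=momentum, weight_decay=weight_decay)
    if name == "rmsprop":
        return RMSprop(params, lr, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}")
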