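"""Gradient-descent optimizers for the layer kit.

SGD implements time-based learning-rate decay, lr_t = lr0 / (1 + decay * t)
with t the epoch index. l1/l2 penalties enter as gradient terms so every
optimizer supports them uniformly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "Nadam", "make_optimizer"]


class _Optimizer:
    def __init__(self, lr: float, decay: float = 0.0, l1: float = 0.0, l2: float = 0.0):
        self.lr0 = lr
        self.decay = decay
        self.l1 = l1
        self.l2 = l2
        self.epoch = 0
        self._step = 0

    @property
    def lr(self) -> float:
        return self.lr0 / (1.0 + self.decay * self.epoch)

    def start_epoch(self, epoch: int) -> None:
        self.epoch = epoch

    def _regularized(self, p: np.ndarray, g: np.ndarray) -> np.ndarray:
        if self.l2:
            g = g + 2.0 * self.l2 * p
        if self.l1:
            g = g + self.l1 * np.sign(p)
        return g

    def update(self, params, grads) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(_Optimizer):
    def update(self, params, grads):
        lr = self.lr
        for p, g in zip(params, grads):
            p -= lr * self._regularized(p, g)


class Adam(_Optimizer):
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def __init__(self, lr: float, **kw):
        super().__init__(lr, **kw)
        self._m: list | None = None

    def _ensure_state(self, params):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]

    def update(self, params, grads):
        self._ensure_state(params)
        self._step += 1
        t, lr = self._step, self.lr
        for p, g, m, v in zip(params, grads, self._m, self._v):
            g = self._regularized(p, g)
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            mhat = m / (1 - self.beta1**t)
            vhat = v / (1 - self.beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class Nadam(Adam):
    """Adam with Nesterov momentum applied to the first-moment estimate."""

    def update(self, params, grads):
        self._ensure_state(params)
        self._step += 1
        t, lr = self._step, self.lr
        for p, g, m, v in zip(params, grads, self._m, self._v):
            g = self._regularized(p, g)
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            mhat = m / (1 - self.beta1 ** (t + 1))
            vhat = v / (1 - self.beta2**t)
            mbar = self.beta1 * mhat + (1 - self.beta1) * g / (1 - self.beta1**t)
            p -= lr * mbar / (np.sqrt(vhat) + self.eps)


_KNOWN = {"sgd": SGD, "adam": Adam, "nadam": Nadam}


def make_optimizer(name: str, lr: float, decay: float = 0.0, l1: float = 0.0, l2: float = 0.0):
    try:
        cls = _KNOWN[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}") from None
    return cls(lr, decay=decay, l1=l1, l2=l2)
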