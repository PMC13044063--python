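"""Stochastic gradient descent and the softmax cross-entropy loss."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "softmax", "cross_entropy"]


class SGD:
    """Minibatch SGD with classical momentum and optional weight decay."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean softmax cross-entropy.

    Returns ``(loss, grad_logits)`` where the gradient is w.r.t. the logits
    and already divided by the batch size.
    """
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), targets].mean()
    grad = np.exp(logp)
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n
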