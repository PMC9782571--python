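"""Minimal dense neural network with manual backprop and Adam.

Sized for feature tables of a few hundred features and a few hundred
injections trained full-batch on one CPU; used by the adversarial
autoencoder in :mod:`metaboflow.normalization`.
"""

from __future__ import annotations

import numpy as np

LEAK = 0.1  # leaky-ReLU negative slope


class MLP:
    """Fully connected net, leaky-ReLU hidden layers, linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He-style init, symmetric for the leaky rectifier
            s = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, s, (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._cache: list[np.ndarray] | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        acts = [X]
        h = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last:
                h = np.where(h > 0, h, LEAK * h)
            acts.append(h)
        if train:
            self._cache = acts
        return h

    def backward(self, dOut: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Gradient of a scalar loss wrt input and params, given dLoss/dOut.

        Requires a preceding ``forward(..., train=True)``.
        """
        acts = self._cache
        if acts is None:
            raise RuntimeError("backward() before forward(train=True)")
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        grad = dOut
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            if i < last:  # undo the activation of this layer's output
                pre_act = acts[i + 1]
                grad = grad * np.where(pre_act > 0, 1.0, LEAK)
            dW[i] = acts[i].T @ grad
            db[i] = grad.sum(axis=0)
            grad = grad @ self.W[i].T
        return grad, dW + db

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean CE and dLoss/dLogits for integer class labels."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def confusion_loss(logits: np.ndarray):
    """CE against the uniform distribution (bounded adversarial objective).

    Minimized when the classifier's softmax is uniform, i.e. the input
    carries no class information.  Returns mean loss and dLoss/dLogits.
    """
    p = softmax(logits)
    n, k = logits.shape
    loss = -np.log(np.clip(p, 1e-12, None)).mean()
    grad = (p - 1.0 / k) / n
    return loss, grad


def clip_grads(grads: list[np.ndarray], max_norm: float) -> list[np.ndarray]:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        grads = [g * scale for g in grads]
    return grads
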