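"""Adam optimisation and the epoch/batch training loop.

The defaults mirror the published regime for this pipeline: Adam with
learning rate 1e-3, beta1 0.9, beta2 0.999, epsilon 1e-7, no decay;
categorical cross-entropy; batch size 100; 50 epochs; a fresh random
permutation of the training set every epoch.
"""

from __future__ import annotations

import numpy as np

from .layers import Sequential, softmax

__all__ = ["Adam", "fit", "one_hot", "cross_entropy"]


class Adam:
    def __init__(self, params: list[np.ndarray], learning_rate: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999,
                 epsilon: float = 1e-7, decay: float = 0.0) -> None:
        if learning_rate < 0 or not (0 <= beta1 < 1) or not (0 <= beta2 < 1):
            raise ValueError("invalid Adam hyperparameters")
        self.params = params
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.decay = decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr = self.lr / (1.0 + self.decay * (self.t - 1))
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.epsilon)


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels out of range")
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def cross_entropy(proba: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    return float(-(onehot * np.log(np.clip(proba, eps, 1.0))).sum() / len(proba))


def fit(model: Sequential, x: np.ndarray, y: np.ndarray, *,
        epochs: int = 50, batch_size: int = 100, learning_rate: float = 0.001,
        beta1: float = 0.9, beta2: float = 0.999, epsilon: float = 1e-7,
        decay: float = 0.0, seed: int = 0, augment=None) -> list[float]:
    """Train ``model`` in place; return the per-epoch mean loss trace.

    Every epoch visits every training example exactly once, in a new
    seeded permutation.  The returned trace has length ``epochs``.
    ``augment``, if given, is called as ``augment(batch, rng)`` on every
    training batch (off by default; no augmentation is the reference
    regime).
    """
    n = len(x)
    if n == 0:
        raise ValueError("empty training set")
    y1h = one_hot(y)
    opt = Adam(model.params, learning_rate, beta1, beta2, epsilon, decay)
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    for _ in range(epochs):
        perm = rng.permutation(n)
        losses = []
        weights = []
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            xb, yb = x[idx], y1h[idx]
            if augment is not None:
                xb = augment(xb, rng)
            logits = model.logits(xb)
            p = softmax(logits)
            losses.append(cross_entropy(p, yb))
            model.backward_from_logits((p - yb) / len(idx))
            opt.step(model.grads)
            weights.append(len(idx))
        trace.append(float(np.average(losses, weights=weights)))
    return trace
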