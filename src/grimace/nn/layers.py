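"""Minimal feed-forward layer framework (numpy, CPU).

Supports exactly the layer vocabulary the rest of the package needs:
2-D convolution (stride 1, zero 'same' padding), 2x2 max-downsampling,
rectified-linear activation, flatten, dense, and a final softmax.  Each
layer caches what its backward pass and the relevance-propagation rules
need; all arithmetic is float32.

Tensor layout is channels-last: images are (N, H, W, C), dense inputs
are (N, D).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "ReLU",
    "Flatten",
    "Dense",
    "Softmax",
    "Sequential",
]


class Layer:
    """Base class: stateless unless a subclass declares parameters."""

    #: learnable arrays, aligned with :attr:`grads`
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2D(Layer):
    """3x3 (by default) convolution, stride 1, zero-padded to keep H and W.

    Weights are stored flattened as (k*k*in_channels, out_channels), viewed
    as one (in_channels, out_channels) block per kernel offset.  The forward
    and backward passes accumulate one matrix product per offset over the
    correspondingly shifted input, which avoids materialising the full patch
    matrix; the relevance-propagation rules reuse the same decomposition.
    """

    def __init__(self, in_channels: int, out_channels: int, ksize: int = 3, *,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if ksize % 2 != 1:
            raise ValueError("ksize must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ksize = ksize
        rng = rng or np.random.default_rng()
        fan_in = ksize * ksize * in_channels
        self.W = _he_init(rng, fan_in, (fan_in, out_channels))
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache: tuple | None = None
        #: set to False by Sequential for the first layer (no earlier layer
        #: consumes the input gradient)
        self.compute_input_grad = True

    @property
    def kernel(self) -> np.ndarray:
        """Weights viewed as (k, k, in_channels, out_channels)."""
        k = self.ksize
        return self.W.reshape(k, k, self.in_channels, self.out_channels)

    def pad(self, x: np.ndarray) -> np.ndarray:
        p = self.ksize // 2
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def patches(self, x: np.ndarray) -> np.ndarray:
        """(N*H*W, k*k*C) patch matrix ordered (ky, kx, channel)."""
        k = self.ksize
        xp = self.pad(x)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        win = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        n, h, w, c = x.shape
        return win.reshape(n * h * w, k * k * c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ValueError(
                f"Conv2D expected (N, H, W, {self.in_channels}), got {x.shape}")
        n, h, w, c = x.shape
        k = self.ksize
        if c * k * k <= 32:
            # few input channels: one matmul over the explicit patch matrix
            cols = self.patches(x)
            out = cols @ self.W + self.b
            self._cache = (x.shape, cols)
            return out.reshape(n, h, w, self.out_channels)
        kern = self.kernel
        xp = self.pad(x)
        out = np.empty((n * h * w, self.out_channels), dtype=np.float32)
        out[:] = self.b
        slices = []
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(xp[:, i:i + h, j:j + w, :])
                xs = xs.reshape(n * h * w, c)
                slices.append(xs)
                out += xs @ kern[i, j]
        self._cache = (x.shape, slices)
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, h, w, c), cache = self._cache
        k = self.ksize
        p = k // 2
        d = np.ascontiguousarray(dout).reshape(n * h * w, self.out_channels)
        self.grads[1][...] = d.sum(axis=0)
        kern = self.kernel
        if c * k * k <= 32:
            cols = cache
            self.grads[0][...] = cols.T @ d
            if not self.compute_input_grad:
                return np.empty(0, dtype=np.float32)
            dcols = (d @ self.W.T).reshape(n, h, w, k, k, c)
            dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
            return dxp[:, p:p + h, p:p + w, :]
        slices = cache
        dW = self.grads[0].reshape(k, k, c, self.out_channels)
        dxp = (np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
               if self.compute_input_grad else None)
        for i in range(k):
            for j in range(k):
                xs = slices[i * k + j]
                dW[i, j] = xs.T @ d
                if dxp is not None:
                    dxp[:, i:i + h, j:j + w, :] += (d @ kern[i, j].T).reshape(n, h, w, c)
        if dxp is None:
            return np.empty(0, dtype=np.float32)
        return dxp[:, p:p + h, p:p + w, :]


class MaxPool2D(Layer):
    """2x2 max-downsampling with stride 2; input H and W must be even."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        if size != 2:
            raise ValueError("only 2x2 pooling is supported")
        self.size = size
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2D needs even spatial dims, got {h}x{w}")
        a = x[:, 0::2, 0::2, :]
        b = x[:, 0::2, 1::2, :]
        cc = x[:, 1::2, 0::2, :]
        d = x[:, 1::2, 1::2, :]
        m_ab = a >= b
        m_cd = cc >= d
        top = np.where(m_ab, a, b)
        bot = np.where(m_cd, cc, d)
        m_tb = top >= bot
        self._cache = (x.shape, m_ab, m_cd, m_tb)
        return np.where(m_tb, top, bot)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Route each output gradient entirely to the window maximum
        (ties broken row-major, so exactly one winner per window)."""
        shape, m_ab, m_cd, m_tb = self._cache
        dx = np.zeros(shape, dtype=np.float32)
        dx[:, 0::2, 0::2, :] = np.where(m_tb & m_ab, dout, np.float32(0))
        dx[:, 0::2, 1::2, :] = np.where(m_tb & ~m_ab, dout, np.float32(0))
        dx[:, 1::2, 0::2, :] = np.where(~m_tb & m_cd, dout, np.float32(0))
        dx[:, 1::2, 1::2, :] = np.where(~m_tb & ~m_cd, dout, np.float32(0))
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.asarray(dout)
        dout *= self._mask  # in place: each backward owns its input buffer
        return dout


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, *,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.in_dim = in_dim
        self.out_dim = out_dim
        rng = rng or np.random.default_rng()
        self.W = _he_init(rng, in_dim, (in_dim, out_dim))
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 2 or x.shape[1] != self.in_dim:
            raise ValueError(f"Dense expected (N, {self.in_dim}), got {x.shape}")
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Softmax(Layer):
    """Terminal normalization layer; backward is never used directly
    (training couples it with the cross-entropy gradient)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return softmax(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise RuntimeError("Softmax.backward is folded into the loss gradient")


class Sequential:
    """Ordered layer container with logits/probability views.

    The last layer must be :class:`Softmax`; ``logits`` stops before it, so
    the explained quantity of the relevance rules (pre-softmax activation)
    is directly accessible.
    """

    def __init__(self, layers: list[Layer]) -> None:
        if not layers or not isinstance(layers[-1], Softmax):
            raise ValueError("Sequential requires a terminal Softmax layer")
        self.layers = layers
        if isinstance(layers[0], Conv2D):
            # nothing consumes the input gradient of the first layer
            layers[0].compute_input_grad = False

    @property
    def feature_layers(self) -> list[Layer]:
        return self.layers[:-1]

    def logits(self, x: np.ndarray) -> np.ndarray:
        for layer in self.feature_layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.logits(x[i:i + batch_size])))
        return np.concatenate(out, axis=0)

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.feature_layers):
            d = layer.backward(d)
        return d

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w
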