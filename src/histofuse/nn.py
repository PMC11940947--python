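"""Minimal CPU neural-network layers used by the bifocal classifier.

Implements exactly what the two-pathway patch classifier needs — 3x3
convolutions (im2col + matmul), ReLU, global average pooling, dense layers,
softmax cross-entropy and an Adam optimizer — with explicit backward passes.
All computation is float32 numpy; with a fixed seed and a single thread the
results are reproducible bit for bit.
"""

from __future__ import annotations

import numpy as np


def _im2col_indices(c: int, h: int, w: int, k: int, stride: int, pad: int):
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    i0 = np.tile(np.repeat(np.arange(k), k), c)
    j0 = np.tile(np.arange(k), k * c)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    ch = np.repeat(np.arange(c), k * k).reshape(-1, 1)
    return ch, i, j, out_h, out_w


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) convolution with stride and zero padding, NCHW layout."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, fan_in)).astype(np.float32)
        b = np.zeros(out_ch, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self._idx_cache: dict[tuple, tuple] = {}

    def _indices(self, h: int, w: int):
        key = (h, w)
        if key not in self._idx_cache:
            self._idx_cache[key] = _im2col_indices(
                self.in_ch, h, w, self.kernel, self.stride, self.pad)
        return self._idx_cache[key]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ch, i, j, out_h, out_w = self._indices(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols = xp[:, ch, i, j]  # (n, c*k*k, out_h*out_w)
        out = np.einsum("fk,nkl->nfl", self.params[0], cols, optimize=True)
        out += self.params[1][None, :, None]
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(n, self.out_ch, out_h, out_w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, out_h, out_w = dout.shape
        dflat = dout.reshape(n, f, out_h * out_w)
        self.grads[0][...] = np.einsum("nfl,nkl->fk", dflat, self._cols,
                                       optimize=True)
        self.grads[1][...] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfl->nkl", self.params[0], dflat, optimize=True)
        _, c, h, w = self._xshape
        ch, i, j, _, _ = self._indices(h, w)
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad),
                       dtype=np.float32)
        np.add.at(dxp, (slice(None), ch, i, j), dcols)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalAvgPool(Layer):
    """(n, c, h, w) -> (n, c): the GAP feature vector of a pathway."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None], (n, c, h, w)
        ).astype(np.float32) / (h * w)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim),
                       size=(in_dim, out_dim)).astype(np.float32)
        b = np.zeros(out_dim, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for layer in self.layers
                for p, g in zip(layer.params, layer.grads)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean 2-class cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
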