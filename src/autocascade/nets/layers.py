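"""Minimal CPU tensor layers with explicit forward/backward passes.

All layers operate on float32 NCHW batches.  Convolutions are realised as
im2col + GEMM; the input gradient of a same-padded convolution is itself a
same-padded convolution with spatially flipped, channel-transposed kernels,
so forward and backward share one code path.  Every layer owns its
parameters as :class:`Param` objects (value + accumulated gradient), which a
separate optimiser updates.

Determinism: all random state (weight init, dropout) comes from generators
passed in explicitly; there is no global RNG use anywhere.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base: subclasses implement forward/backward and expose params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix for a same-padded conv."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    n, c, h, w = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Conv2D(Layer):
    """k×k same-padded convolution, stride 1 (k odd)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, cout)))
        self.b = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, _, h, w = x.shape
        cols = _im2col(x, self.k, self.k // 2)
        out = cols @ self.W.value + self.b.value
        if training:
            self._cols, self._shape = cols, x.shape
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.grad += self._cols.T @ dmat
        self.b.grad += dmat.sum(axis=0)
        # input gradient = conv of dout with flipped kernels, channels swapped
        w_sp = self.W.value.reshape(self.cin, self.k, self.k, self.cout)
        w_flip = w_sp[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.cout * self.k * self.k, self.cin
        )
        cols = _im2col(dout, self.k, self.k // 2)
        dx = (cols @ w_flip).reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)
        self._cols = None
        return np.ascontiguousarray(dx)


class BatchNorm2D(Layer):
    """Per-channel batch normalisation; eps 1e-5, running-stat momentum 0.9."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if training:
            self._cache = (xhat, invstd)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dbeta = dout.sum(axis=(0, 2, 3))
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        coef = (self.gamma.value * invstd / m)[None, :, None, None]
        dx = coef * (m * dout - dbeta[None, :, None, None] - xhat * dgamma[None, :, None, None])
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; ties resolve to the first occurrence."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = np.ascontiguousarray(r).reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        dx = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class UpConv2(Layer):
    """Stride-2 transposed convolution with a 2×2 kernel (exact 2× upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout, 2, 2)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        out = np.einsum("nchw,cfij->nfhiwj", x, self.W.value, optimize=True)
        out = out.reshape(n, self.cout, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        if training:
            self._x = x
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h2, w2 = dout.shape
        dr = dout.reshape(n, f, h2 // 2, 2, w2 // 2, 2)
        self.W.grad += np.einsum("nchw,nfhiwj->cfij", self._x, dr, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dx = np.einsum("nfhiwj,cfij->nchw", dr, self.W.value, optimize=True)
        self._x = None
        return np.ascontiguousarray(dx.astype(np.float32))


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate, self.rng = rate, rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class SqueezeExcite(Layer):
    """Channel recalibration: global average pool -> C/r -> ReLU -> C -> sigmoid."""

    def __init__(self, c: int, ratio: int, rng: np.random.Generator):
        hidden = max(c // ratio, 1)
        self.W1 = Param(rng.normal(0.0, np.sqrt(2.0 / c), (c, hidden)))
        self.b1 = Param(np.zeros(hidden))
        self.W2 = Param(rng.normal(0.0, np.sqrt(2.0 / hidden), (hidden, c)))
        self.b2 = Param(np.zeros(c))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x.mean(axis=(2, 3))
        h_pre = z @ self.W1.value + self.b1.value
        h = np.maximum(h_pre, 0.0)
        s = 1.0 / (1.0 + np.exp(-(h @ self.W2.value + self.b2.value)))
        if training:
            self._cache = (x, z, h_pre, h, s)
        return x * s[:, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, z, h_pre, h, s = self._cache
        hw = x.shape[2] * x.shape[3]
        dx = dout * s[:, :, None, None]
        ds = (dout * x).sum(axis=(2, 3))
        dpre2 = ds * s * (1.0 - s)
        self.W2.grad += h.T @ dpre2
        self.b2.grad += dpre2.sum(axis=0)
        dh = (dpre2 @ self.W2.value.T) * (h_pre > 0)
        self.W1.grad += z.T @ dh
        self.b1.grad += dh.sum(axis=0)
        dz = dh @ self.W1.value.T
        dx += dz[:, :, None, None] / hw
        self._cache = None
        return dx.astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout
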