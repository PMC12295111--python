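"""Layers with forward/backward passes on NCHW numpy arrays."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride 1 unless stated, explicit zero padding.

    ``padding`` is an integer pad width or ``"same"`` (odd kernels only),
    so a pad of 2 with a 3x3 kernel grows each spatial side by 2, the map
    by 4 — the convention used by the classifier trace (128 -> 130 etc.).
    """

    def __init__(self, cin: int, cout: int, k: int = 3, padding="same", stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        if padding == "same":
            if k % 2 == 0:
                raise ValueError("'same' padding requires an odd kernel")
            padding = (k - 1) // 2
        self.pad = int(padding)
        scale = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU stacks
        self.W = Param(rng.normal(0.0, scale, size=(cin * k * k, cout)))
        self.b = Param(np.zeros(cout))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.W, self.b]

    @property
    def n_parameters(self) -> int:
        return (self.k * self.k * self.cin + 1) * self.cout

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        return ho, wo

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        assert c == self.cin, f"expected {self.cin} channels, got {c}"
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.W.value + self.b.value
        if training:
            self._cols = cols
            self._xshape = (n, c, h, w, ho, wo)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w, ho, wo = self._xshape
        p, k, s = self.pad, self.k, self.stride
        dflat = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.W.grad = self._cols.T @ dflat
        self.b.grad = dflat.sum(axis=0)
        dcols = (dflat @ self.W.value.T).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    @property
    def n_parameters(self) -> int:
        return 2 * self.gamma.value.size

    def forward(self, x, training=False):
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            ivar = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
            self._cache = (xhat, ivar)
            return g * xhat + b
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * ivar[None, :, None, None]
        return g * xhat + b

    def backward(self, grad):
        xhat, ivar = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad = (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = grad * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (ivar[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class _Pool2D(Layer):
    """2x2 pooling with stride 2; odd trailing rows/columns are dropped
    (floor division), matching 67 -> 33 style shape traces."""

    def __init__(self):
        self._shape = None

    @staticmethod
    def out_shape(h: int, w: int) -> tuple[int, int]:
        return h // 2, w // 2

    def _windows(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        self._shape = (n, c, h, w, h2, w2)
        return xc.reshape(n, c, h2, 2, w2, 2)


class AvgPool2D(_Pool2D):
    def forward(self, x, training=False):
        return self._windows(x).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w, h2, w2 = self._shape
        dx = np.zeros((n, c, h, w))
        up = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        dx[:, :, : 2 * h2, : 2 * w2] = up
        return dx


class MaxPool2D(_Pool2D):
    def forward(self, x, training=False):
        win = self._windows(x)
        n, c, h2, _, w2, _ = win.shape
        flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._arg = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w, h2, w2 = self._shape
        dflat = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dflat, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.nin, self.nout = nin, nout
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.W, self.b]

    @property
    def n_parameters(self) -> int:
        return (self.nin + 1) * self.nout

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.W.value.T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class PixelSoftmax(Layer):
    """Softmax over the channel axis of an NCHW map (per-pixel classes)."""

    def forward(self, x, training=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=1, keepdims=True))


class Upsample2D(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, training=False):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for l in self.layers:
            if isinstance(l, BatchNorm2D):
                state.append(l.running_mean.copy())
                state.append(l.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value = v.copy()
        i = len(ps)
        for l in self.layers:
            if isinstance(l, BatchNorm2D):
                l.running_mean = state[i].copy()
                l.running_var = state[i + 1].copy()
                i += 2

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())
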