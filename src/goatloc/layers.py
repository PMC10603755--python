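"""Minimal trainable layers with explicit forward/backward passes.

Everything operates on ``(N, C, H, W)`` float arrays (or ``(N, F)`` for
dense layers).  Each layer caches what its backward pass needs, returns
the gradient w.r.t. its input, and accumulates parameter gradients in
``Param.grad``.  This is intentionally not an autograd system: the layer
set is exactly what the shallow SE detector and the FC regressors need,
and every backward pass is verified against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr

from .counting import LayerSpec


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def shape(self):
        return self.value.shape


class Layer:
    def params(self) -> list[Param]:
        return []

    def layer_specs(self) -> list[LayerSpec]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _kaiming_uniform(rng, fan_in: int, shape, dtype):
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Layer):
    """k x k convolution with 'same' padding, implemented via im2col."""

    def __init__(self, cin, cout, kernel=3, stride=1, bias=True, rng=None,
                 dtype=np.float32):
        rng = np.random.default_rng(rng)
        self.cin, self.cout, self.kernel, self.stride = cin, cout, kernel, stride
        fan_in = kernel * kernel * cin
        self.w = Param(_kaiming_uniform(rng, fan_in, (cout, cin * kernel * kernel), dtype))
        self.b = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def layer_specs(self):
        return [LayerSpec("conv", cin=self.cin, cout=self.cout, kernel=self.kernel,
                          stride=self.stride, bias=self.b is not None)]

    def _im2col(self, x):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.kernel // 2
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, k * k, ho, wo), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i * k + j] = xp[:, :, i:i + ho * s:s, j:j + wo * s:s]
        return cols.reshape(n, c * k * k, ho * wo), (n, c, h, w, ho, wo)

    def forward(self, x):
        cols, dims = self._im2col(x)
        n, _, _, _, ho, wo = dims
        out = np.matmul(self.w.value[None], cols)  # (n, cout, ho*wo)
        if self.b is not None:
            out += self.b.value[None, :, None]
        self._cache = (cols, dims)
        return out.reshape(n, self.cout, ho, wo)

    def backward(self, dy):
        cols, (n, c, h, w, ho, wo) = self._cache
        k, s, p = self.kernel, self.stride, self.kernel // 2
        dflat = dy.reshape(n, self.cout, ho * wo)
        self.w.grad += np.einsum("nol,ncl->oc", dflat, cols, optimize=True)
        if self.b is not None:
            self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T[None], dflat)  # (n, c*k*k, ho*wo)
        dcols = dcols.reshape(n, c, k * k, ho, wo)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += dcols[:, :, i * k + j]
        return dxp[:, :, p:p + h, p:p + w]


class Linear(Layer):
    def __init__(self, cin, cout, bias=True, rng=None, dtype=np.float32):
        rng = np.random.default_rng(rng)
        self.cin, self.cout = cin, cout
        self.w = Param(_kaiming_uniform(rng, cin, (cout, cin), dtype))
        self.b = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self._x = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def layer_specs(self):
        return [LayerSpec("linear", cin=self.cin, cout=self.cout, bias=self.b is not None)]

    def forward(self, x):
        self._x = x
        y = x @ self.w.value.T
        if self.b is not None:
            y += self.b.value
        return y

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class PixelLayerNorm(Layer):
    """Layer norm over the channel axis at every spatial position."""

    def __init__(self, channels, eps=1e-6, dtype=np.float32):
        self.channels, self.eps = channels, eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def layer_specs(self):
        return [LayerSpec("norm", channels=self.channels)]

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class GELU(Layer):
    def forward(self, x):
        self._x = x
        return x * ndtr(x)

    def backward(self, dy):
        x = self._x
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return dy * (ndtr(x) + x * pdf)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate (bias-free bottleneck)."""

    def __init__(self, channels, reduction=4, rng=None, dtype=np.float32):
        if channels % reduction != 0:
            raise ValueError("channels must be divisible by reduction")
        rng = np.random.default_rng(rng)
        self.channels, self.reduction = channels, reduction
        hidden = channels // reduction
        self.w1 = Param(_kaiming_uniform(rng, channels, (hidden, channels), dtype))
        self.w2 = Param(_kaiming_uniform(rng, hidden, (channels, hidden), dtype))
        self._cache = None

    def params(self):
        return [self.w1, self.w2]

    def layer_specs(self):
        hidden = self.channels // self.reduction
        return [
            LayerSpec("linear", cin=self.channels, cout=hidden, bias=False),
            LayerSpec("linear", cin=hidden, cout=self.channels, bias=False),
        ]

    def forward(self, x):
        n, c, h, w = x.shape
        z = x.mean(axis=(2, 3))  # (n, c)
        h1 = z @ self.w1.value.T
        a = np.maximum(h1, 0.0)
        s = expit(a @ self.w2.value.T)
        self._cache = (x, z, h1, a, s, h * w)
        return x * s[:, :, None, None]

    def backward(self, dy):
        x, z, h1, a, s, hw = self._cache
        ds = (dy * x).sum(axis=(2, 3))
        dx = dy * s[:, :, None, None]
        dh2 = ds * s * (1.0 - s)
        self.w2.grad += dh2.T @ a
        da = dh2 @ self.w2.value
        dh1 = np.where(h1 > 0, da, 0.0)
        self.w1.grad += dh1.T @ z
        dz = dh1 @ self.w1.value
        dx += dz[:, :, None, None] / hw
        return dx


class NearestUpsample2x(Layer):
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def layer_specs(self):
        return [s for layer in self.layers for s in layer.layer_specs()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Param], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def n_params(layer: Layer) -> int:
    """Framework-style enumeration: sum of actual weight array sizes."""
    return sum(p.value.size for p in layer.params())
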