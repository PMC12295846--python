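"""Minimal reverse-mode neural-network layers on NumPy arrays.

Every layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``; parameters
accumulate gradients in-place. Feature volumes are channels-last:
``(batch, time, height, width, channels)``.

The only global mode is :func:`guided_gradients`, which switches every ReLU
backward pass to the guided-backpropagation rule (negative incoming
gradients are suppressed in addition to the forward mask).
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Sequential",
    "SpatialConv",
    "TemporalConv",
    "PointwiseConv",
    "Dense",
    "LayerNorm",
    "ReLU",
    "Sigmoid",
    "GlobalAvgPool",
    "MaxPool3D",
    "Adam",
    "softmax",
    "cross_entropy_from_logits",
    "guided_gradients",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised for structurally invalid layer or architecture settings."""


_GUIDED = False


@contextmanager
def guided_gradients():
    """Context in which ReLU backward passes use the guided-backprop rule."""
    global _GUIDED
    prev = _GUIDED
    _GUIDED = True
    try:
        yield
    finally:
        _GUIDED = prev


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: children and params are discovered from attribute order."""

    def children(self):
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                yield name, attr

    def _own_params(self):
        for name, attr in vars(self).items():
            if isinstance(attr, Param):
                yield name, attr

    def params(self) -> list[Param]:
        return [p for _, p in self.named_params()]

    def named_params(self, prefix: str = ""):
        out = []
        for name, p in self._own_params():
            out.append((prefix + name, p))
        for name, child in self.children():
            out.extend(child.named_params(prefix + name + "."))
        return out

    def n_params(self, include_bias: bool = True) -> int:
        total = 0
        for name, p in self.named_params():
            if not include_bias and name.rsplit(".", 1)[-1] == "b":
                continue
            total += p.value.size
        return total

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self.layers = list(layers)

    def children(self):
        for i, layer in enumerate(self.layers):
            yield f"layer{i}", layer

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Variance-scaling fan-in ('He') initialization."""
    return rng.standard_normal(shape) * math.sqrt(2.0 / max(fan_in, 1))


class SpatialConv(Module):
    """1 x k x k convolution over (H, W), stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k < 1 or k % 2 == 0:
            raise ConfigurationError(f"spatial kernel must be odd and positive, got {k}")
        self.k = k
        self.w = Param(_he_normal(rng, (k, k, c_in, c_out), k * k * c_in))
        self.b = Param(np.zeros(c_out))

    def forward(self, x):
        k = self.k
        p = k // 2
        self._xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(self._xp, (k, k), axis=(2, 3))  # B,T,H,W,C,k,k
        out = np.tensordot(win, self.w.value, axes=([5, 6, 4], [0, 1, 2]))
        return out + self.b.value

    def backward(self, g):
        k = self.k
        p = k // 2
        win = sliding_window_view(self._xp, (k, k), axis=(2, 3))
        gw = np.tensordot(win, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))  # C,k,k,O
        self.w.grad += gw.transpose(1, 2, 0, 3)
        self.b.grad += g.sum(axis=(0, 1, 2, 3))
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p), (0, 0)))
        gwin = sliding_window_view(gp, (k, k), axis=(2, 3))  # B,T,H,W,O,k,k
        wt = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)  # k,k,O,C
        return np.tensordot(gwin, wt, axes=([5, 6, 4], [0, 1, 2]))


class TemporalConv(Module):
    """t x 1 x 1 convolution over the time axis, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, t: int, rng: np.random.Generator):
        if t < 1 or t % 2 == 0:
            raise ConfigurationError(f"temporal kernel must be odd and positive, got {t}")
        self.t = t
        self.w = Param(_he_normal(rng, (t, c_in, c_out), t * c_in))
        self.b = Param(np.zeros(c_out))

    def forward(self, x):
        t = self.t
        p = t // 2
        self._xp = np.pad(x, ((0, 0), (p, p), (0, 0), (0, 0), (0, 0)))
        win = sliding_window_view(self._xp, t, axis=1)  # B,T,H,W,C,t
        return np.tensordot(win, self.w.value, axes=([5, 4], [0, 1])) + self.b.value

    def backward(self, g):
        t = self.t
        p = t // 2
        win = sliding_window_view(self._xp, t, axis=1)
        gw = np.tensordot(win, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))  # C,t,O
        self.w.grad += gw.transpose(1, 0, 2)
        self.b.grad += g.sum(axis=(0, 1, 2, 3))
        gp = np.pad(g, ((0, 0), (p, p), (0, 0), (0, 0), (0, 0)))
        gwin = sliding_window_view(gp, t, axis=1)  # B,T,H,W,O,t
        wt = self.w.value[::-1].transpose(0, 2, 1)  # t,O,C
        return np.tensordot(gwin, wt, axes=([5, 4], [0, 1]))


class PointwiseConv(Module):
    """1 x 1 x 1 convolution: a per-position linear map over channels."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = Param(_he_normal(rng, (c_in, c_out), c_in))
        self.b = Param(np.zeros(c_out))

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        self.w.grad += np.tensordot(self._x, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        self.b.grad += g.sum(axis=(0, 1, 2, 3))
        return g @ self.w.value.T


class Dense(Module):
    """Fully connected layer on (batch, features) inputs."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_he_normal(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out))

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class LayerNorm(Module):
    """Normalizes over the trailing (channel) axis with learned scale/offset.

    eps follows the Keras LayerNormalization default (1e-3); a smaller eps
    sharply amplifies gradients wherever the channel vector is nearly
    constant (e.g. black image regions).
    """

    def __init__(self, c: int, eps: float = 1e-3):
        self.eps = eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g):
        xhat, inv = self._xhat, self._inv
        axes = tuple(range(g.ndim - 1))
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gh = g * self.gamma.value
        m1 = gh.mean(axis=-1, keepdims=True)
        m2 = (gh * xhat).mean(axis=-1, keepdims=True)
        return inv * (gh - m1 - xhat * m2)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        g = g * self._mask
        if _GUIDED:
            g = g * (g > 0)
        return g


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class GlobalAvgPool(Module):
    """Average over (time, height, width), producing (batch, channels)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, g):
        B, T, H, W, C = self._shape
        return np.broadcast_to(
            g[:, None, None, None, :], self._shape
        ) / float(T * H * W)


class MaxPool3D(Module):
    """2x2 spatial max pooling, optionally 2x temporal, with ceil semantics.

    Odd extents are padded with -inf so the output size is ceil(extent/2);
    the temporal axis is pooled only when it has length >= 2.
    """

    def __init__(self, pool_time: bool = True):
        self.pool_time = pool_time

    def forward(self, x):
        B, T, H, W, C = x.shape
        if H < 2 or W < 2:
            raise ConfigurationError(f"spatial extents must be >= 2 to pool, got {H}x{W}")
        pt = 2 if (self.pool_time and T >= 2) else 1
        To, Ho, Wo = -(-T // pt), -(-H // 2), -(-W // 2)
        xp = np.pad(
            x,
            ((0, 0), (0, To * pt - T), (0, Ho * 2 - H), (0, Wo * 2 - W), (0, 0)),
            constant_values=-np.inf,
        )
        xr = (
            xp.reshape(B, To, pt, Ho, 2, Wo, 2, C)
            .transpose(0, 1, 3, 5, 7, 2, 4, 6)
            .reshape(B, To, Ho, Wo, C, pt * 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._in_shape = (B, T, H, W, C)
        self._pt = pt
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        B, T, H, W, C = self._in_shape
        pt = self._pt
        Bo, To, Ho, Wo, Co = g.shape
        gr = np.zeros((Bo, To, Ho, Wo, Co, pt * 4))
        np.put_along_axis(gr, self._idx[..., None], g[..., None], axis=-1)
        gp = (
            gr.reshape(Bo, To, Ho, Wo, Co, pt, 2, 2)
            .transpose(0, 1, 5, 2, 6, 3, 7, 4)
            .reshape(Bo, To * pt, Ho * 2, Wo * 2, Co)
        )
        return gp[:, :T, :H, :W, :]


class Adam(Module):
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def zero_grad(self):
        for p in self._params:
            p.grad[...] = 0.0

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self._t
        bias2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self._params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_from_logits(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy on integer labels.

    Returns ``(loss, dlogits, probs)``; the softmax is applied inside the
    loss so the model itself emits raw logits.
    """
    labels = np.asarray(labels)
    n = logits.shape[0]
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = float(-logp[np.arange(n), labels].mean())
    p = np.exp(logp)
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, d / n, p
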