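"""Layer primitives (NHWC, float32).

Every layer exposes ``forward(*inputs, retain=False)`` and
``backward(grad_out) -> tuple of grads w.r.t. inputs``; parameter
gradients accumulate into ``self.grads``. ``retain=True`` caches whatever
the backward pass needs — plain inference skips the caches to keep big
backbones cheap.

Activations flatten row-major in NHWC order; that convention is part of
the feature-vector contract and is pinned by a regression test.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ShapeError


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.frozen = False
        self._cache = None

    def forward(self, *xs, retain: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> tuple[np.ndarray, ...]:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self):
        self.grads = {}

    def _accumulate(self, name, g):
        if name in self.grads:
            self.grads[name] += g
        else:
            self.grads[name] = g


class Conv2d(Layer):
    """2-D convolution via im2col. Weights shaped (kh, kw, c_in, c_out)."""

    def __init__(self, c_in, c_out, kernel, stride=1, pad=0, rng=None, bias=True):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * c_in
        self.params["W"] = he_init(rng, (kernel, kernel, c_in, c_out), fan_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32) if bias else None
        if not bias:
            del self.params["b"]

    def _im2col(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (N, Ho, Wo, C, k, k) -> cols (N*Ho*Wo, k*k*C)
        n, ho, wo = win.shape[:3]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, k * k * self.c_in)
        return np.ascontiguousarray(cols), (n, ho, wo)

    def forward(self, x, retain=False):
        if x.shape[3] != self.c_in:
            raise ShapeError(f"conv expected {self.c_in} channels, got {x.shape[3]}")
        cols, (n, ho, wo) = self._im2col(x.astype(np.float32, copy=False))
        k = self.kernel
        # cols layout is (k, k, c_in) flattened; W is stored in the same order
        wmat = self.params["W"].reshape(k * k * self.c_in, self.c_out)
        out = cols @ wmat
        if "b" in self.params:
            out += self.params["b"]
        out = out.reshape(n, ho, wo, self.c_out)
        if retain:
            self._cache = (cols, x.shape)
        return out

    def backward(self, gout):
        cols, x_shape = self._cache
        n, ho, wo, _ = gout.shape
        k, s, p = self.kernel, self.stride, self.pad
        g2 = gout.reshape(-1, self.c_out)
        gw = (cols.T @ g2).reshape(k, k, self.c_in, self.c_out)
        self._accumulate("W", gw)
        if "b" in self.params:
            self._accumulate("b", g2.sum(axis=0))
        wmat = self.params["W"].reshape(k * k * self.c_in, self.c_out)
        gcols = (g2 @ wmat.T).reshape(n, ho, wo, k, k, self.c_in)
        hp, wp = x_shape[1] + 2 * p, x_shape[2] + 2 * p
        dxp = np.zeros((n, hp, wp, self.c_in), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += gcols[:, :, :, i, j, :]
        dx = dxp[:, p:hp - p, p:wp - p, :] if p else dxp
        return (dx,)


class Linear(Layer):
    def __init__(self, d_in, d_out, rng=None):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        rng = rng or np.random.default_rng(0)
        self.params["W"] = he_init(rng, (d_in, d_out), d_in)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x, retain=False):
        if x.shape[-1] != self.d_in:
            raise ShapeError(f"linear expected width {self.d_in}, got {x.shape[-1]}")
        if retain:
            self._cache = x
        return x.astype(np.float32, copy=False) @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        x = self._cache
        self._accumulate("W", x.T @ gout)
        self._accumulate("b", gout.sum(axis=0))
        return (gout @ self.params["W"].T,)


class ReLU(Layer):
    def forward(self, x, retain=False):
        out = np.maximum(x, 0)
        if retain:
            self._cache = x > 0
        return out

    def backward(self, gout):
        return (gout * self._cache,)


class MaxPool2d(Layer):
    """Max pooling; padding (if any) is filled with -inf so it never wins."""

    def __init__(self, kernel, stride, pad=0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def _padded(self, x):
        p = self.pad
        if not p:
            return x
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), constant_values=-np.inf)

    def forward(self, x, retain=False):
        k, s = self.kernel, self.stride
        xp = self._padded(x)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        out = win.max(axis=(4, 5))
        if retain:
            self._cache = (xp, out, x.shape)
        return out

    def backward(self, gout):
        xp, out, x_shape = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        n, ho, wo, c = gout.shape
        dxp = np.zeros(xp.shape, dtype=np.float32)
        remaining = gout.copy()
        for i in range(k):
            for j in range(k):
                sl = (slice(None), slice(i, i + s * ho, s), slice(j, j + s * wo, s))
                hit = (xp[sl] == out) & (remaining != 0)
                dxp[sl] += np.where(hit, remaining, 0.0)
                remaining = np.where(hit, 0.0, remaining)
        dx = dxp[:, p:xp.shape[1] - p, p:xp.shape[2] - p, :] if p else dxp
        return (dx[:, :x_shape[1], :x_shape[2], :],)


class GlobalAvgPool(Layer):
    """Spatial mean: (N, H, W, C) -> (N, C)."""

    def forward(self, x, retain=False):
        if retain:
            self._cache = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gout):
        n, h, w, c = self._cache
        return (np.broadcast_to(gout[:, None, None, :] / (h * w), (n, h, w, c)).astype(
            np.float32).copy(),)


class Flatten(Layer):
    """Row-major flatten of everything after the batch axis."""

    def forward(self, x, retain=False):
        if retain:
            self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return (gout.reshape(self._cache),)


class Softmax(Layer):
    def forward(self, x, retain=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=-1, keepdims=True)
        if retain:
            self._cache = out
        return out

    def backward(self, gout):
        y = self._cache
        return (y * (gout - (gout * y).sum(axis=-1, keepdims=True)),)


class Add(Layer):
    def forward(self, a, b, retain=False):
        return a + b

    def backward(self, gout):
        return (gout, gout)


class Concat(Layer):
    """Channel-axis concatenation (last axis)."""

    def forward(self, *xs, retain=False):
        if retain:
            self._cache = [x.shape[-1] for x in xs]
        return np.concatenate(xs, axis=-1)

    def backward(self, gout):
        splits = np.cumsum(self._cache)[:-1]
        return tuple(np.ascontiguousarray(g) for g in np.split(gout, splits, axis=-1))
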