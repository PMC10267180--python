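"""Layers with explicit forward/backward passes.

Every layer implements ``forward(x, train=False, rng=None)``, ``backward(g)``
and ``params()``.  Gradients accumulate into ``Param.grad`` during
``backward`` and are consumed by the optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_EPS = 1e-5


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.standard_normal((n_in, n_out)) * scale)
        self.b = Param(np.zeros(n_out))

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T

    def params(self):
        return [self.w, self.b]


class Conv1d(Layer):
    """1-D convolution with 'same' padding via im2col matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = Param(rng.standard_normal((c_out, c_in * kernel)) * scale)
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel // 2

    def forward(self, x, train=False, rng=None):
        bsz, c_in, t = x.shape
        if c_in != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c_in}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        # (B, C, T, k) -> (B, T, C*k)
        cols = sliding_window_view(xp, self.k, axis=2)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(bsz, t, self.c_in * self.k)
        self._cols, self._t = cols, t
        y = cols @ self.w.value.T + self.b.value  # (B, T, Cout)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, g):
        bsz, _, t = g.shape
        gt = g.transpose(0, 2, 1)  # (B, T, Cout)
        self.w.grad += np.einsum("btc,btk->ck", gt, self._cols)
        self.b.grad += gt.sum(axis=(0, 1))
        dcols = gt @ self.w.value  # (B, T, Cin*k)
        dcols = dcols.reshape(bsz, t, self.c_in, self.k).transpose(0, 2, 1, 3)
        dxp = np.zeros((bsz, self.c_in, t + self.k - 1))
        for j in range(self.k):
            dxp[:, :, j : j + t] += dcols[:, :, :, j]
        return dxp[:, :, self.pad_l : self.pad_l + t]

    def params(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class PReLU(Layer):
    """Parametric ReLU with one learnable negative-side slope per channel."""

    def __init__(self, channels: int, init: float = 0.25):
        self.a = Param(np.full((channels, 1), init))

    def forward(self, x, train=False, rng=None):
        self._x = x
        return np.where(x > 0, x, self.a.value * x)

    def backward(self, g):
        neg = np.minimum(self._x, 0.0)
        self.a.grad += (g * neg).sum(axis=(0, 2))[:, None]
        return np.where(self._x > 0, g, self.a.value * g)

    def params(self):
        return [self.a]


class Dropout(Layer):
    def __init__(self, p: float):
        if not (0.0 <= p < 1.0):
            raise ValueError(f"dropout rate must lie in [0, 1), got {p}")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time); running stats at inference."""

    def __init__(self, channels: int, momentum: float = 0.9):
        self.gamma = Param(np.ones((channels, 1)))
        self.beta = Param(np.zeros((channels, 1)))
        self.run_mean = np.zeros((channels, 1))
        self.run_var = np.ones((channels, 1))
        self.momentum = momentum

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 2), keepdims=True)[0]
            var = x.var(axis=(0, 2), keepdims=True)[0]
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            self._m = x.shape[0] * x.shape[2]
        else:
            mean, var = self.run_mean, self.run_var
        self._inv = 1.0 / np.sqrt(var + _EPS)
        self._xhat = (x - mean) * self._inv
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g):
        self.gamma.grad += (g * self._xhat).sum(axis=(0, 2))[:, None]
        self.beta.grad += g.sum(axis=(0, 2))[:, None]
        gx = g * self.gamma.value
        if not self._train:
            return gx * self._inv
        m = self._m
        s1 = gx.sum(axis=(0, 2), keepdims=True)
        s2 = (gx * self._xhat).sum(axis=(0, 2), keepdims=True)
        return self._inv * (gx - s1 / m - self._xhat * s2 / m)


class InstanceNorm1d(Layer):
    """Per-sample, per-channel standardization over time, learnable affine."""

    def __init__(self, channels: int):
        self.gamma = Param(np.ones((channels, 1)))
        self.beta = Param(np.zeros((channels, 1)))

    def forward(self, x, train=False, rng=None):
        mean = x.mean(axis=2, keepdims=True)
        var = x.var(axis=2, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + _EPS)
        self._xhat = (x - mean) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g):
        self.gamma.grad += (g * self._xhat).sum(axis=(0, 2))[:, None]
        self.beta.grad += g.sum(axis=(0, 2))[:, None]
        gx = g * self.gamma.value
        t = g.shape[2]
        s1 = gx.mean(axis=2, keepdims=True)
        s2 = (gx * self._xhat).mean(axis=2, keepdims=True)
        return self._inv * (gx - s1 - self._xhat * s2)

    def params(self):
        return [self.gamma, self.beta]


# BatchNorm affine params are registered via the same interface
BatchNorm1d.params = lambda self: [self.gamma, self.beta]  # type: ignore[method-assign]


class MaxPool1d(Layer):
    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, x, train=False, rng=None):
        bsz, c, t = x.shape
        t_out = t // self.f
        xr = x[:, :, : t_out * self.f].reshape(bsz, c, t_out, self.f)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, g):
        bsz, c, t_out = g.shape
        dxr = np.zeros((bsz, c, t_out, self.f))
        np.put_along_axis(dxr, self._arg[..., None], g[..., None], axis=3)
        dx = np.zeros(self._shape)
        dx[:, :, : t_out * self.f] = dxr.reshape(bsz, c, t_out * self.f)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g):
        return np.repeat(g[:, :, None], self._t, axis=2) / self._t


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class AttentionSplit(Layer):
    """Time-wise attention: split channels in half, softmax the second half
    over the time axis, and use it as multiplicative weights for the first.

    If the weight half is constant over time the softmax is uniform (1/T), so
    the output is the data half divided by T.
    """

    @staticmethod
    def time_softmax(b: np.ndarray) -> np.ndarray:
        e = np.exp(b - b.max(axis=2, keepdims=True))
        return e / e.sum(axis=2, keepdims=True)

    def forward(self, x, train=False, rng=None):
        c = x.shape[1]
        if c % 2:
            raise ValueError(f"attention split needs an even channel count, got {c}")
        h = c // 2
        self._a = x[:, :h]
        self._s = self.time_softmax(x[:, h:])
        self.last_attention = self._s  # inspectable: sums to 1 over time
        return self._a * self._s

    def backward(self, g):
        da = g * self._s
        ds = g * self._a
        s = self._s
        db = s * (ds - (ds * s).sum(axis=2, keepdims=True))
        return np.concatenate([da, db], axis=1)


class ResidualBlock(Layer):
    """conv(k1)-BN-ReLU -> conv(k2)-BN-ReLU -> conv(k3)-BN, plus a shortcut
    (1x1 conv + BN when the channel count changes), then ReLU."""

    def __init__(self, c_in: int, c_out: int, kernels: tuple[int, int, int], rng: np.random.Generator):
        k1, k2, k3 = kernels
        self.body: list[Layer] = [
            Conv1d(c_in, c_out, k1, rng), BatchNorm1d(c_out), ReLU(),
            Conv1d(c_out, c_out, k2, rng), BatchNorm1d(c_out), ReLU(),
            Conv1d(c_out, c_out, k3, rng), BatchNorm1d(c_out),
        ]
        if c_in != c_out:
            self.shortcut: list[Layer] = [Conv1d(c_in, c_out, 1, rng), BatchNorm1d(c_out)]
        else:
            self.shortcut = []
        self.out_relu = ReLU()

    def forward(self, x, train=False, rng=None):
        h = x
        for layer in self.body:
            h = layer.forward(h, train, rng)
        s = x
        for layer in self.shortcut:
            s = layer.forward(s, train, rng)
        return self.out_relu.forward(h + s, train, rng)

    def backward(self, g):
        g = self.out_relu.backward(g)
        gh = g
        for layer in reversed(self.body):
            gh = layer.backward(gh)
        gs = g
        for layer in reversed(self.shortcut):
            gs = layer.backward(gs)
        return gh + gs

    def params(self):
        out: list[Param] = []
        for layer in self.body + self.shortcut:
            out.extend(layer.params())
        return out
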