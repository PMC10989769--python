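"""A small, deterministic numpy neural-network engine.

Provides exactly the layers needed by the spectral residual classifier and
the dilated-convolution segmentation network: 1-D and 2-D convolutions
(tap-loop formulation so the inner products run in BLAS), batch
normalisation, ReLU, dense layers, parameter-free residual shortcuts,
softmax cross-entropy (optionally pixel-weighted) and Adam.

Every layer implements ``forward(x, train)`` and ``backward(dout)``;
backward consumes the cache left by the immediately preceding forward.
Gradients are hand-derived and covered by numerical-gradient tests.
All randomness is injected through a ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1d",
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "Dense",
    "Flatten",
    "Sequential",
    "ResidualBlock1d",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution on (N, C, L) with 'same'-style zero padding.

    Output length is ``(L + 2*(k//2) - k)//stride + 1``.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k))  # He initialisation
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, k // 2

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        N, C, L = x.shape
        k, s, p = self.k, self.stride, self.pad
        Lo = (L + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._xp_shape = xp.shape
        self._segs = [xp[:, :, t : t + s * Lo : s][:, :, :Lo] for t in range(k)]
        out = np.empty((N, self.W.value.shape[0], Lo))
        out[:] = self.b.value[None, :, None]
        for t in range(k):
            out += np.einsum("oc,ncl->nol", self.W.value[:, :, t], self._segs[t], optimize=True)
        return out

    def backward(self, dout):
        k, s = self.k, self.stride
        Lo = dout.shape[2]
        dxp = np.zeros(self._xp_shape)
        self.b.grad += dout.sum(axis=(0, 2))
        for t in range(k):
            self.W.grad[:, :, t] += np.einsum("nol,ncl->oc", dout, self._segs[t], optimize=True)
            view = dxp[:, :, t : t + s * Lo : s]
            view[:, :, :Lo] += np.einsum(
                "oc,nol->ncl", self.W.value[:, :, t], dout, optimize=True
            )
        self._segs = None
        p = self.pad
        return dxp[:, :, p : dxp.shape[2] - p] if p else dxp


class Conv2d(Layer):
    """2-D dilated convolution on (N, C, H, W); stride 1, shape-preserving."""

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.d = k, dilation
        self.pad = dilation * (k // 2)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        N, C, H, Wd = x.shape
        k, d, p = self.k, self.d, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp_shape = xp.shape
        self._segs = {}
        out = np.empty((N, self.W.value.shape[0], H, Wd))
        out[:] = self.b.value[None, :, None, None]
        for i in range(k):
            for j in range(k):
                seg = xp[:, :, i * d : i * d + H, j * d : j * d + Wd]
                self._segs[(i, j)] = seg
                out += np.einsum(
                    "oc,nchw->nohw", self.W.value[:, :, i, j], seg, optimize=True
                )
        return out

    def backward(self, dout):
        k, d, p = self.k, self.d, self.pad
        N, _, H, Wd = dout.shape
        dxp = np.zeros(self._xp_shape)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        for i in range(k):
            for j in range(k):
                self.W.grad[:, :, i, j] += np.einsum(
                    "nohw,nchw->oc", dout, self._segs[(i, j)], optimize=True
                )
                dxp[:, :, i * d : i * d + H, j * d : j * d + Wd] += np.einsum(
                    "oc,nohw->nchw", self.W.value[:, :, i, j], dout, optimize=True
                )
        self._segs = None
        return dxp[:, :, p : p + H, p : p + Wd] if p else dxp


class BatchNorm(Layer):
    """Per-channel batch normalisation for (N, C, ...) tensors."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    @staticmethod
    def _bshape(x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=True):
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shp)) * self._inv_std.reshape(shp)
        self._axes, self._m = axes, x.size // x.shape[1]
        return self.gamma.value.reshape(shp) * self._xhat + self.beta.value.reshape(shp)

    def backward(self, dout):
        shp = self._bshape(dout)
        axes, m = self._axes, self._m
        self.gamma.grad += (dout * self._xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value.reshape(shp)
        dxhat = dout * g
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shp)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes).reshape(shp) / m
        )
        dx = term * self._inv_std.reshape(shp)
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def _shortcut_1d(x: np.ndarray, stride: int, cout: int) -> np.ndarray:
    """Parameter-free residual shortcut: subsample and zero-pad channels."""
    if stride > 1:
        x = x[:, :, ::stride]
    cin = x.shape[1]
    if cout > cin:
        pad = np.zeros((x.shape[0], cout - cin, x.shape[2]))
        x = np.concatenate([x, pad], axis=1)
    return x


class ResidualBlock1d(Layer):
    """Two k-tap convolutions with batch norm and an identity shortcut.

    When the block downsamples (stride 2) or widens, the shortcut
    subsamples the input and zero-pads channels so the conv-layer count is
    unaffected by the skip path.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng):
        self.conv1 = Conv1d(cin, cout, k, stride=stride, rng=rng)
        self.bn1 = BatchNorm(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(cout, cout, k, stride=1, rng=rng)
        self.bn2 = BatchNorm(cout)
        self.relu_out = ReLU()
        self.stride, self.cin, self.cout = stride, cin, cout

    def params(self):
        return [
            p
            for l in (self.conv1, self.bn1, self.conv2, self.bn2)
            for p in l.params()
        ]

    def forward(self, x, train=True):
        self._xin_shape = x.shape
        h = self.bn1.forward(self.conv1.forward(x, train), train)
        h = self.relu1.forward(h, train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        sc = _shortcut_1d(x, self.stride, self.cout)
        # stride arithmetic can differ by one point; trim to match
        n = min(h.shape[2], sc.shape[2])
        self._trim = (h.shape[2], sc.shape[2], n)
        return self.relu_out.forward(h[:, :, :n] + sc[:, :, :n], train)

    def backward(self, dout):
        dsum = self.relu_out.backward(dout)
        h_len, sc_len, n = self._trim
        dh = np.zeros((dsum.shape[0], self.cout, h_len))
        dh[:, :, :n] = dsum
        dx_main = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(dh)))
            )
        )
        # shortcut gradient: undo zero-pad (drop extra channels) and
        # scatter back through the subsampling
        dsc = np.zeros((dsum.shape[0], self.cout, sc_len))
        dsc[:, :, :n] = dsum
        dsc = dsc[:, : self.cin, :]
        dx = np.zeros(self._xin_shape)
        if self.stride > 1:
            dx[:, :, :: self.stride] += dsc
        else:
            dx += dsc
        # main-path input may have been consumed at full length
        return dx_main + dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean (optionally weighted) cross-entropy over the leading axes.

    ``logits``: (..., K); ``labels``: integer array matching the leading
    shape; ``weights``: per-example nonnegative weights (same leading
    shape).  Returns the scalar loss and d(loss)/d(logits).
    """
    p = softmax(logits)
    flat_p = p.reshape(-1, p.shape[-1])
    flat_y = labels.reshape(-1)
    n = flat_y.size
    if weights is None:
        w = np.ones(n)
    else:
        w = weights.reshape(-1).astype(float)
    wsum = w.sum()
    eps = 1e-12
    loss = float(-(w * np.log(flat_p[np.arange(n), flat_y] + eps)).sum() / wsum)
    dflat = flat_p.copy()
    dflat[np.arange(n), flat_y] -= 1.0
    dflat *= (w / wsum)[:, None]
    return loss, dflat.reshape(logits.shape)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
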