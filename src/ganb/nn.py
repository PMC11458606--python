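"""Minimal feed-forward neural network layers with analytic backprop.

Everything is plain numpy on float64.  Layers cache what their backward
pass needs; parameters and gradients are exposed as parallel lists so the
optimizers can treat a whole network as a flat sequence of arrays.
Convolutions use im2col/col2im; transposed convolution is implemented as
the adjoint of the corresponding convolution, which makes its gradient an
ordinary convolution.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "Sequential",
    "SGD",
    "Adam",
    "gradient_step",
    "im2col",
    "col2im",
]

# sigmoid outputs are clipped into this open interval so downstream
# log-likelihood terms stay finite
SIGMOID_EPS = 1e-7


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold (n, c, h, w) into (n, c*k*k, oh*ow) patch columns."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow)


def col2im(cols: np.ndarray, out_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back onto the grid."""
    n, c, h, w = out_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Layer:
    """Base class; stateless layers keep the default empty param list."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Conv2d(Layer):
    """Strided convolution on (n, c, h, w) batches."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x_shape = x.shape
        n, c, h, w = x.shape
        oh = (h + 2 * self.pad - self.k) // self.stride + 1
        ow = (w + 2 * self.pad - self.k) // self.stride + 1
        self._cols = im2col(x, self.k, self.stride, self.pad)
        y = np.einsum("oc,ncl->nol", self.W, self._cols) + self.b[None, :, None]
        return y.reshape(n, self.c_out, oh, ow)

    def backward(self, dy):
        n = dy.shape[0]
        dyf = dy.reshape(n, self.c_out, -1)
        self.dW[...] = np.einsum("nol,ncl->oc", dyf, self._cols)
        self.db[...] = dyf.sum(axis=(0, 2))
        dcols = np.einsum("oc,nol->ncl", self.W, dyf)
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed (fractionally strided) convolution; upsamples by `stride`."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_in, c_out * k * k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h - 1) * self.stride - 2 * self.pad + self.k,
                (w - 1) * self.stride - 2 * self.pad + self.k)

    def forward(self, x):
        n, c, h, w = x.shape
        self._in_hw = (h, w)
        self._xf = x.reshape(n, c, h * w)
        oh, ow = self.out_hw(h, w)
        cols = np.einsum("ck,ncl->nkl", self.W, self._xf)
        y = col2im(cols, (n, self.c_out, oh, ow), self.k, self.stride, self.pad)
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        n = dy.shape[0]
        dcols = im2col(dy, self.k, self.stride, self.pad)
        self.dW[...] = np.einsum("ncl,nkl->ck", self._xf, dcols)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        dx = np.einsum("ck,nkl->ncl", self.W, dcols)
        h, w = self._in_hw
        return dx.reshape(n, self.c_in, h, w)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Layer):
    def forward(self, x):
        y = 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable logistic
        y = np.clip(y, SIGMOID_EPS, 1.0 - SIGMOID_EPS)
        self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        self.shape = shape

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class SGD:
    """Plain gradient descent: theta <- theta - eta * grad."""

    def __init__(self, lr: float):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr = lr

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g in zip(params, grads):
            p -= self.lr * g


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def gradient_step(params: list[np.ndarray], grads: list[np.ndarray], lr: float,
                  optimizer: SGD | Adam | None = None) -> list[np.ndarray]:
    """Apply one descent update in place and return the parameter list.

    With no optimizer this is the plain rule theta <- theta - lr * grad;
    passing an :class:`Adam` instance keeps its moment state across calls.
    Raises on non-finite gradients, naming the offending parameter index.
    """
    for idx, g in enumerate(grads):
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for parameter {idx}")
    opt = optimizer if optimizer is not None else SGD(lr)
    if isinstance(opt, SGD):
        opt.lr = lr
    opt.step(params, grads)
    return params
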