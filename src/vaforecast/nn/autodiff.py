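"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the package's networks need: broadcasted
arithmetic, 2-D matrix products, pointwise nonlinearities, reductions,
reshapes, concatenation, basic slicing, strided 2-D convolution (im2col)
and nearest-neighbour upsampling. Gradients are accumulated by a
topological backward sweep; correctness is pinned by finite-difference
tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample_nearest", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._prev = tuple(prev)
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing -------------------------------------------------

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- arithmetic -----------------------------------------------------

    def _coerce(self, other):
        return other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw():
            self.grad += _unbroadcast(out.grad, self.data.shape)
            other.grad += _unbroadcast(out.grad, other.data.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw():
            self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __pow__(self, p):
        out = Tensor(self.data ** p, (self,))

        def bw():
            self.grad += out.grad * p * self.data ** (p - 1)

        out._backward = bw
        return out

    def matmul(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw():
            self.grad += out.grad @ other.data.T
            other.grad += self.data.T @ out.grad

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))

        def bw():
            self.grad += out.grad * (1.0 - y * y)

        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, (self,))

        def bw():
            self.grad += out.grad * y * (1.0 - y)

        out._backward = bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))

        def bw():
            self.grad += out.grad * mask

        out._backward = bw
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), (self,))

        def bw():
            self.grad += out.grad * sign

        out._backward = bw
        return out

    # -- reductions / shape ---------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), (self,))

        def bw():
            self.grad += out.grad  # broadcasts scalar

        out._backward = bw
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), (self,))

        def bw():
            self.grad += out.grad / n

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def bw():
            self.grad += out.grad.reshape(self.data.shape)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw():
            g = np.zeros_like(self.data)
            g[idx] = out.grad
            self.grad += g

        out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw():
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            t.grad += g

    out._backward = bw
    return out


# -- convolution -------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int, oh: int, ow: int):
    n, c, h, w = x_shape
    cols = cols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution; x is (N, C, H, W), weight (OC, C, k, k), bias (OC,)."""
    oc, c, k, _ = weight.data.shape
    cols, oh, ow = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(oc, c * k * k)
    y = np.einsum("of,nfp->nop", wmat, cols) + bias.data[None, :, None]
    out = Tensor(y.reshape(-1, oc, oh, ow), (x, weight, bias))

    def bw():
        g = out.grad.reshape(-1, oc, oh * ow)
        weight.grad += np.einsum("nop,nfp->of", g, cols).reshape(weight.data.shape)
        bias.grad += g.sum(axis=(0, 2))
        gcols = np.einsum("of,nop->nfp", wmat, g)
        x.grad += _col2im(gcols, x.data.shape, k, stride, pad, oh, ow)

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    out = Tensor(x.data.repeat(factor, axis=2).repeat(factor, axis=3), (x,))

    def bw():
        n, c, h, w = x.data.shape
        g = out.grad.reshape(n, c, h, factor, w, factor)
        x.grad += g.sum(axis=(3, 5))

    out._backward = bw
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
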