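"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements the small set of tensor operations the binding model needs
(broadcast arithmetic, matmul, reductions, activations, indexing,
concatenation) with float64 storage. Gradients are accumulated by a
topological-order backward sweep. The op surface mirrors numpy so that
math written against :class:`Tensor` also runs on plain ndarrays (see
:mod:`mgbind.nn.functional`).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and backward graph."""

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._prev = tuple(_prev)
        self._backward = _backward

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, _prev=parents, _backward=backward)

    def _acc(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # ---------------------------------------------------------------- backward
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._acc(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            self._acc(_unbroadcast(g, self.data.shape))
            other._acc(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            self._acc(_unbroadcast(g * other.data, self.data.shape))
            other._acc(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            self._acc(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bwd(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._acc(_unbroadcast(ga, a.shape))
            other._acc(_unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), bwd)

    # ------------------------------------------------------------- activations
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._acc(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._acc(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def abs(self):
        def bwd(g):
            self._acc(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._acc(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def bwd(g):
            self._acc(g * factor)

        return self._make(self.data * factor, (self,), bwd)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)

        def bwd(g):
            self._acc(g * np.where(self.data > 0, 1.0, neg + alpha))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = _stable_sigmoid(self.data)

        def bwd(g):
            self._acc(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._acc(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bwd)

    def sqrt(self):
        return self**0.5

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._acc(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            expanded = out_data
            if axis is not None and not keepdims:
                expanded = np.expand_dims(out_data, axis)
                g = np.expand_dims(g, axis)
            mask = (self.data == expanded).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)  # ties share gradient
            self._acc(g * mask)

        return self._make(out_data, (self,), bwd)

    def softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # ------------------------------------------------------------ shape & index
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            self._acc(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes=None):
        if axes is None:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            self._acc(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)

    @property
    def T(self):
        return self.transpose()

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._acc(full)

        return self._make(out_data, (self,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors (or arrays) along ``axis`` with gradient flow."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            t._acc(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)
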