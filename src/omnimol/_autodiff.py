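"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape-based engine sized for desk-scale molecular models: float64
throughout, dense numpy under every op, no device or dtype dispatch. Supports
broadcasting binary ops, (batched) matmul, reductions, gather/scatter for
graph message passing, and the handful of nonlinearities the model uses.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "gather", "scatter_add"]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(p for p in _parents if p.requires_grad)
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                a, b = self.data, other.data
                if a.ndim == 1 and b.ndim == 1:        # dot product
                    ga, gb = g * b, g * a
                elif b.ndim == 1:                       # (..., n, k) @ (k,)
                    ga = np.multiply.outer(g, b)
                    gb = (a * np.expand_dims(g, -1)).reshape(-1, b.shape[0]).sum(axis=0)
                elif a.ndim == 1:                       # (k,) @ (..., k, m)
                    ga = (np.expand_dims(g, -2) @ b.swapaxes(-1, -2)).reshape(-1, a.shape[0]).sum(axis=0)
                    gb = np.multiply.outer(a, g) if b.ndim == 2 else np.einsum("k,...m->...km", a, g)
                else:                                   # (batched) matrix products
                    ga = _unbroadcast(g @ b.swapaxes(-1, -2), a.shape)
                    gb = _unbroadcast(a.swapaxes(-1, -2) @ g, b.shape)
                if self.requires_grad:
                    self._accum(ga)
                if other.requires_grad:
                    other._accum(gb)
            out._backward = bwd
        return out

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def gelu(self):
        """Exact Gaussian-error-linear unit: x * Phi(x)."""
        phi = 0.5 * (1.0 + erf(self.data / _SQRT2))
        out = Tensor(self.data * phi, _parents=(self,))
        if out.requires_grad:
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * self.data**2)
            out._backward = lambda g: self._accum(g * (phi + self.data * pdf))
        return out

    def abs(self):
        """|x| with subgradient sign(x) at 0."""
        out = Tensor(np.abs(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclipped."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        if out.requires_grad:
            mask = (self.data > lo) & (self.data < hi)
            out._backward = lambda g: self._accum(g * mask)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        if out.requires_grad:
            def bwd(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, self.data.shape).copy())
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))
        if out.requires_grad:
            def bwd(g):
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))
            out._backward = bwd
        return out

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        if out.requires_grad:
            inv = np.argsort(axes) if axes is not None else None
            out._backward = lambda g: self._accum(g.transpose(inv) if inv is not None else g.transpose())
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))
        if out.requires_grad:
            def bwd(g):
                gg = np.zeros_like(self.data)
                np.add.at(gg, idx, g)
                self._accum(gg)
            out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bwd
    return out


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of `t` (axis 0) by an integer index array."""
    return t[np.asarray(index, dtype=np.intp)]


def scatter_add(values: Tensor, index: np.ndarray, n_rows: int) -> Tensor:
    """Sum rows of `values` into an (n_rows, ...) output at positions `index`."""
    values = Tensor._lift(values)
    index = np.asarray(index, dtype=np.intp)
    data = np.zeros((n_rows,) + values.data.shape[1:])
    np.add.at(data, index, values.data)
    out = Tensor(data, _parents=(values,))
    if out.requires_grad:
        out._backward = lambda g: values._accum(g[index])
    return out
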