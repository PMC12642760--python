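"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape: each ``Tensor`` wraps a float64 ndarray and remembers the
parents and backward rule that produced it.  Supports the operations the
recurrent actor-critic and PPO loss need (matmul, elementwise arithmetic,
tanh/sigmoid/exp/log/softplus, gammaln/digamma for Beta log-densities,
reductions, clip, minimum, where) with full NumPy broadcasting.  Gradients
are checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy import special

__all__ = ["Tensor", "constant", "parameter", "matmul", "tanh", "sigmoid",
           "exp", "log", "softplus", "gammaln", "digamma", "minimum",
           "clip", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    # make ndarray <op> Tensor dispatch to the reflected Tensor methods
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction -------------------------------------------

    def _make(self, data, parents, backward):
        return Tensor(data, parents, backward)

    def __add__(self, other):
        other = _as_tensor(other)
        out = self._make(self.data + other.data, (self, other),
                         lambda g: (_unbroadcast(g, self.shape),
                                    _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return self._make(self.data * other.data, (self, other),
                          lambda g: (_unbroadcast(g * other.data, self.shape),
                                     _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self._make(self.data / other.data, (self, other),
                          lambda g: (_unbroadcast(g / other.data, self.shape),
                                     _unbroadcast(-g * self.data / other.data ** 2,
                                                  other.shape)))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, k: float):
        assert isinstance(k, (int, float))
        return self._make(self.data ** k, (self,),
                          lambda g: (g * k * self.data ** (k - 1),))

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        return self._make(self.data[idx], (self,), backward)

    def reshape(self, *shape):
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old),))

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- backward pass -------------------------------------------------

    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if p.requires_grad:
                    if p.grad is None:
                        p.grad = np.zeros_like(p.data)
                    p.grad += g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(a.data @ b.data, (a, b),
                  lambda g: (g @ b.data.swapaxes(-1, -2),
                             _unbroadcast(a.data.swapaxes(-1, -2) @ g, b.shape)))


def tanh(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    y = np.tanh(x.data)
    return Tensor(y, (x,), lambda g: (g * (1.0 - y ** 2),))


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    y = special.expit(x.data)
    return Tensor(y, (x,), lambda g: (g * y * (1.0 - y),))


def exp(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    y = np.exp(x.data)
    return Tensor(y, (x,), lambda g: (g * y,))


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    return Tensor(np.log(x.data), (x,), lambda g: (g / x.data,))


def softplus(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    y = np.logaddexp(0.0, x.data)
    return Tensor(y, (x,), lambda g: (g * special.expit(x.data),))


def gammaln(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    return Tensor(special.gammaln(x.data), (x,),
                  lambda g: (g * special.digamma(x.data),))


def digamma(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    return Tensor(special.digamma(x.data), (x,),
                  lambda g: (g * special.polygamma(1, x.data),))


def minimum(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    mask = a.data <= b.data
    return Tensor(np.where(mask, a.data, b.data), (a, b),
                  lambda g: (_unbroadcast(g * mask, a.shape),
                             _unbroadcast(g * ~mask, b.shape)))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    x = _as_tensor(x)
    inside = (x.data >= lo) & (x.data <= hi)
    return Tensor(np.clip(x.data, lo, hi), (x,), lambda g: (g * inside,))


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]

    def backward(g):
        return tuple(np.split(g, np.cumsum(sizes)[:-1], axis=axis))

    return Tensor(np.concatenate([t.data for t in ts], axis=axis), tuple(ts), backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor(np.stack([t.data for t in ts], axis=axis), tuple(ts), backward)
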