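"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to train the tabular attention classifier on a CPU:
broadcast-aware elementwise ops, batched matmul, reductions, reshaping,
concatenation, an embedding gather and erf (for exact GELU).  Gradients are
accumulated by a topological backward pass; correctness is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # ------------------------------------------------------------ operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0)) if isinstance(other, Tensor) else mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    # convenience
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward, requires: bool) -> Tensor:
    out = Tensor(data, requires_grad=requires)
    if requires:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


# ------------------------------------------------------------------ basics

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data
    req = a.requires_grad or b.requires_grad

    def backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad, b.data.shape))

    out = _make(out_data, (a, b), backward, req)
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data
    req = a.requires_grad or b.requires_grad

    def backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad * a.data, b.data.shape))

    out = _make(out_data, (a, b), backward, req)
    return out


def power(a, exponent: float) -> Tensor:
    a = _wrap(a)

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * exponent * a.data ** (exponent - 1))

    out = _make(a.data**exponent, (a,), backward, a.requires_grad)
    return out


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * out_data)

    out = _make(out_data, (a,), backward, a.requires_grad)
    return out


def log(a) -> Tensor:
    a = _wrap(a)

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad / a.data)

    out = _make(np.log(a.data), (a,), backward, a.requires_grad)
    return out


def erf(a) -> Tensor:
    a = _wrap(a)

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * (2.0 / np.sqrt(np.pi)) * np.exp(-a.data**2))

    out = _make(special.erf(a.data), (a,), backward, a.requires_grad)
    return out


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = np.matmul(a.data, b.data)
    req = a.requires_grad or b.requires_grad

    def backward():
        g = out.grad
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out = _make(out_data, (a, b), backward, req)
    return out


# --------------------------------------------------------------- reductions

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward():
        if not a.requires_grad:
            return
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis=axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out = _make(out_data, (a,), backward, a.requires_grad)
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


# ------------------------------------------------------------ shape surgery

def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    orig = a.data.shape

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad.reshape(orig))

    out = _make(a.data.reshape(shape), (a,), backward, a.requires_grad)
    return out


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    inv = np.argsort(axes)

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad.transpose(inv))

    out = _make(a.data.transpose(axes), (a,), backward, a.requires_grad)
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])

    out = _make(out_data, tuple(tensors), backward, req)
    return out


def gather_rows(table: Tensor, index: np.ndarray) -> Tensor:
    """Embedding lookup: ``table[index]`` with scatter-add backward."""
    index = np.asarray(index, dtype=int)

    def backward():
        if table.requires_grad:
            g = np.zeros_like(table.data)
            np.add.at(g, index.reshape(-1), out.grad.reshape(-1, table.data.shape[-1]))
            table._accumulate(g)

    out = _make(table.data[index], (table,), backward, table.requires_grad)
    return out


# ------------------------------------------------------- composite non-lin

_SQRT2 = np.sqrt(2.0)


def gelu(x: Tensor) -> Tensor:
    """Exact GELU: 0.5 x (1 + erf(x / sqrt 2))."""
    return mul(mul(x, 0.5), add(erf(mul(x, 1.0 / _SQRT2)), 1.0))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant, no grad
    e = exp(add(x, -shift))
    return mul(e, power(tsum(e, axis=axis, keepdims=True), -1.0))


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = tmean(x, axis=-1, keepdims=True)
    xc = add(x, mul(mu, -1.0))
    var = tmean(mul(xc, xc), axis=-1, keepdims=True)
    xn = mul(xc, power(add(var, eps), -0.5))
    return add(mul(xn, gain), bias)
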