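"""Tape-based reverse-mode automatic differentiation on numpy arrays.

Minimal engine carrying the package's neural networks and manifold
operations.  A :class:`Tensor` wraps an ``ndarray`` and records the
operations applied to it; :meth:`Tensor.backward` walks the tape in
reverse topological order and accumulates gradients.

Every function in this module also accepts plain ``ndarray`` (or scalar)
inputs, in which case it computes with numpy directly and returns an
``ndarray`` — so the geometry code can be written once and used both
inside the training graph and as ordinary vectorised numpy.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (undo numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    # make numpy defer binary ops to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(other, mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(other, power(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    g = _unbroadcast(g, t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad or p._parents)
    if live:
        out.requires_grad = True
        out._parents = live
        out._backward = backward
    return out


def _binary(a, b, fwd, bwd_a, bwd_b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return fwd(np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64))
    ta, tb = as_tensor(a), as_tensor(b)
    data = fwd(ta.data, tb.data)

    def backward(g):
        if ta.requires_grad or ta._parents:
            _accum(ta, bwd_a(g, ta.data, tb.data, data))
        if tb.requires_grad or tb._parents:
            _accum(tb, bwd_b(g, ta.data, tb.data, data))

    return _node(data, (ta, tb), backward)


def _unary(a, fwd, bwd):
    if not _is_tensor(a):
        return fwd(np.asarray(a, dtype=np.float64))
    data = fwd(a.data)

    def backward(g):
        _accum(a, bwd(g, a.data, data))

    return _node(data, (a,), backward)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    return _binary(a, b, lambda x, y: x + y,
                   lambda g, x, y, o: g, lambda g, x, y, o: g)


def mul(a, b):
    return _binary(a, b, lambda x, y: x * y,
                   lambda g, x, y, o: g * y, lambda g, x, y, o: g * x)


def power(a, p: float):
    if not _is_tensor(a):
        return np.asarray(a, dtype=np.float64) ** p
    data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1))

    return _node(data, (a,), backward)


def matmul(a, b):
    return _binary(
        a, b, lambda x, y: x @ y,
        lambda g, x, y, o: _matmul_bwd_a(g, x, y),
        lambda g, x, y, o: _matmul_bwd_b(g, x, y),
    )


def _matmul_bwd_a(g, x, y):
    if y.ndim == 1:
        return np.multiply.outer(g, y) if g.ndim else g * y
    return g @ np.swapaxes(y, -1, -2)


def _matmul_bwd_b(g, x, y):
    if x.ndim == 1:
        return np.multiply.outer(x, g) if g.ndim else x * g
    return np.swapaxes(x, -1, -2) @ g


# ---------------------------------------------------------------------------
# elementwise transcendental
# ---------------------------------------------------------------------------

def exp(a):
    return _unary(a, np.exp, lambda g, x, o: g * o)


def log(a):
    return _unary(a, np.log, lambda g, x, o: g / x)


def log1p(a):
    return _unary(a, np.log1p, lambda g, x, o: g / (1.0 + x))


def sqrt(a):
    return _unary(a, np.sqrt, lambda g, x, o: g * 0.5 / o)


def sin(a):
    return _unary(a, np.sin, lambda g, x, o: g * np.cos(x))


def cos(a):
    return _unary(a, np.cos, lambda g, x, o: -g * np.sin(x))


def sinh(a):
    return _unary(a, np.sinh, lambda g, x, o: g * np.cosh(x))


def cosh(a):
    return _unary(a, np.cosh, lambda g, x, o: g * np.sinh(x))


def tanh(a):
    return _unary(a, np.tanh, lambda g, x, o: g * (1.0 - o * o))


def arccosh(a):
    # domain guard: derivative blows up at 1; callers clamp upstream
    return _unary(a, np.arccosh,
                  lambda g, x, o: g / np.sqrt(np.maximum(x * x - 1.0, 1e-30)))


def arccos(a):
    return _unary(a, np.arccos,
                  lambda g, x, o: -g / np.sqrt(np.maximum(1.0 - x * x, 1e-30)))


def softplus(a):
    def fwd(x):
        return np.logaddexp(0.0, x)

    return _unary(a, fwd, lambda g, x, o: g * _sp.expit(x))


def gelu(a):
    """Gaussian Error Linear Unit, exact (Phi-based) form."""

    def fwd(x):
        return x * _sp.ndtr(x)

    def bwd(g, x, o):
        return g * (_sp.ndtr(x) + x * np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi))

    return _unary(a, fwd, bwd)


def gammaln(a):
    return _unary(a, _sp.gammaln, lambda g, x, o: g * _sp.digamma(x))


def maximum(a, floor: float):
    """Elementwise max with a constant; gradient passes where a > floor."""
    return _unary(a, lambda x: np.maximum(x, floor),
                  lambda g, x, o: g * (x > floor))


def minimum(a, ceil: float):
    return _unary(a, lambda x: np.minimum(x, ceil),
                  lambda g, x, o: g * (x < ceil))


def clip(a, lo: float, hi: float):
    return minimum(maximum(a, lo), hi)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def sum(a, axis=None, keepdims=False):
    if not _is_tensor(a):
        return np.sum(a, axis=axis, keepdims=keepdims)
    data = np.sum(a.data, axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(ax % a.data.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _node(data, (a,), backward)


def mean(a, axis=None, keepdims=False):
    if not _is_tensor(a):
        return np.mean(a, axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape):
    if not _is_tensor(a):
        return np.reshape(a, shape)
    data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _node(data, (a,), backward)


def take(a, idx):
    if not _is_tensor(a):
        return np.asarray(a)[idx]
    data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        _accum(a, full)

    return _node(data, (a,), backward)


def concat(parts, axis=-1):
    if not any(_is_tensor(p) for p in parts):
        return np.concatenate(parts, axis=axis)
    tparts = [as_tensor(p) for p in parts]
    data = np.concatenate([p.data for p in tparts], axis=axis)
    sizes = [p.data.shape[axis] for p in tparts]

    def backward(g):
        splits = np.cumsum(sizes)[:-1]
        for p, chunk in zip(tparts, np.split(g, splits, axis=axis)):
            if p.requires_grad or p._parents:
                _accum(p, chunk)

    return _node(data, tuple(tparts), backward)


def stack(parts, axis=0):
    expanded = [reshape(p, _expand_shape(p, axis)) for p in parts]
    return concat(expanded, axis=axis)


def _expand_shape(p, axis):
    shape = list(p.shape if _is_tensor(p) else np.shape(p))
    shape.insert(axis if axis >= 0 else len(shape) + 1 + axis, 1)
    return tuple(shape)


def logsumexp(a, axis=-1, keepdims=False):
    if not _is_tensor(a):
        return _sp.logsumexp(a, axis=axis, keepdims=keepdims)
    m = np.max(a.data, axis=axis, keepdims=True)
    shifted = add(a, Tensor(-m))
    s = log(sum(exp(shifted), axis=axis, keepdims=True))
    out = add(s, Tensor(m))
    if not keepdims:
        out = reshape(out, np.squeeze(out.data, axis=axis).shape)
    return out


def softmax(a, axis=-1):
    return exp(add(a, mul(logsumexp(a, axis=axis, keepdims=True), -1.0)))


def where_const(cond: np.ndarray, a, b):
    """Select between two branches with a constant (non-differentiated) mask."""
    c = np.asarray(cond)
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.where(c, a, b)
    ta, tb = as_tensor(a), as_tensor(b)
    data = np.where(c, ta.data, tb.data)

    def backward(g):
        if ta.requires_grad or ta._parents:
            _accum(ta, np.where(c, g, 0.0))
        if tb.requires_grad or tb._parents:
            _accum(tb, np.where(c, 0.0, g))

    return _node(data, (ta, tb), backward)


def detach(a):
    return a.detach() if _is_tensor(a) else np.asarray(a)


def value(a) -> np.ndarray:
    """The underlying ndarray, whether or not `a` is on the tape."""
    return a.data if _is_tensor(a) else np.asarray(a)
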