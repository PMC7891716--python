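"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network here is small (a handful of affine maps, leaky rectifiers and
row-wise log-softmaxes), so a compact tape is all that is needed: each
:class:`Var` records its parents and a closure that routes the incoming
gradient to them.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand's shape.

Only the primitives the model uses are implemented.  Gradient correctness
is enforced by finite-difference tests at 1e-4 relative tolerance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var",
    "concat",
    "leaky_relu",
    "log_softmax",
    "clip",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were expanded from 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Var:
    """A node in the computation graph: a value, a gradient slot, a backward rule."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _wrap(other) -> "Var":
        return other if isinstance(other, Var) else Var(np.asarray(other, dtype=np.float64))

    @property
    def shape(self):
        return self.value.shape

    def __repr__(self):
        return f"Var(shape={self.value.shape})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Var._wrap(other)

        def backward(g, a=self, b=other):
            a.grad += _unbroadcast(g, a.value.shape)
            b.grad += _unbroadcast(g, b.value.shape)

        return Var(self.value + other.value, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a.grad += -g

        return Var(-self.value, (self,), backward)

    def __sub__(self, other):
        return self + (-Var._wrap(other))

    def __rsub__(self, other):
        return Var._wrap(other) + (-self)

    def __mul__(self, other):
        other = Var._wrap(other)

        def backward(g, a=self, b=other):
            a.grad += _unbroadcast(g * b.value, a.value.shape)
            b.grad += _unbroadcast(g * a.value, b.value.shape)

        return Var(self.value * other.value, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Var):
            raise TypeError("division only by python/numpy scalars")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = Var._wrap(other)

        def backward(g, a=self, b=other):
            a.grad += g @ b.value.T
            b.grad += a.value.T @ g

        return Var(self.value @ other.value, (self, other), backward)

    def exp(self):
        out_val = np.exp(self.value)

        def backward(g, a=self, v=out_val):
            a.grad += g * v

        return Var(out_val, (self,), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a.grad += np.broadcast_to(g, a.value.shape).copy()

        return Var(self.value.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- autodiff driver -------------------------------------------------
    def backward(self):
        """Accumulate d(self)/d(node) into every reachable node's ``.grad``."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar root")
        order: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)


def concat(vars_: list[Var], axis: int = -1) -> Var:
    """Concatenate along `axis`; gradient splits back to the operands."""
    vs = [Var._wrap(v) for v in vars_]
    sizes = [v.value.shape[axis] for v in vs]
    offsets = np.cumsum([0] + sizes)

    def backward(g, vs=vs, offsets=offsets, ax=axis):
        for v, lo, hi in zip(vs, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[ax] = slice(lo, hi)
            v.grad += g[tuple(idx)]

    return Var(np.concatenate([v.value for v in vs], axis=axis), tuple(vs), backward)


def leaky_relu(x: Var, slope: float = 0.01) -> Var:
    x = Var._wrap(x)
    mask = x.value >= 0

    def backward(g, a=x, m=mask, s=slope):
        a.grad += g * np.where(m, 1.0, s)

    return Var(np.where(mask, x.value, slope * x.value), (x,), backward)


def log_softmax(x: Var, axis: int = -1) -> Var:
    """Row-wise log-softmax; numerically stabilised by max subtraction."""
    x = Var._wrap(x)
    shifted = x.value - x.value.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_val = shifted - lse

    def backward(g, a=x, out=out_val, ax=axis):
        a.grad += g - np.exp(out) * g.sum(axis=ax, keepdims=True)

    return Var(out_val, (x,), backward)


def clip(x: Var, lo: float, hi: float) -> Var:
    """Clamp values; gradient is passed through only inside the interval."""
    x = Var._wrap(x)
    mask = (x.value >= lo) & (x.value <= hi)

    def backward(g, a=x, m=mask):
        a.grad += g * m

    return Var(np.clip(x.value, lo, hi), (x,), backward)
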