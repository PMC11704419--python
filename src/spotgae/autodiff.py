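"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The graph-attention model needs gradients through dense matrix products,
sparse neighborhood aggregation (gather / scatter-add over edge lists),
per-node softmax, and the cosine reconstruction loss.  This module provides
exactly those primitives on float64 arrays: a :class:`Tensor` wrapping a
value plus vector-Jacobian-product closures, and a topological-order
``backward``.  Everything is double precision so closed-form oracles can be
matched to ~1e-10.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "parameter",
    "add", "sub", "mul", "div", "neg", "matmul", "transpose", "reshape",
    "gather", "segment_sum", "sigmoid", "elu", "exp", "sqrt",
    "power", "tsum", "tmean",
]


class Tensor:
    """A node in the computation graph.

    ``parents`` is a list of ``(parent_tensor, vjp)`` pairs where ``vjp``
    maps the output gradient to the parent's gradient contribution.
    Constant tensors carry no parents, so the backward sweep never visits
    subgraphs that cannot influence a parameter.
    """

    __slots__ = ("value", "grad", "parents", "requires_grad")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = tuple(parents)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in self.parents
        )
        if not self.requires_grad:
            self.parents = ()
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node.parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node.grad is None:
                continue
            for parent, vjp in node.parents:
                if not parent.requires_grad:
                    continue
                g = vjp(node.grad)
                parent.grad = g if parent.grad is None else parent.grad + g

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def constant(value) -> Tensor:
    return Tensor(value)


def parameter(value) -> Tensor:
    return Tensor(value, requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.value + b.value, [
        (a, lambda g: _unbroadcast(g, a.value.shape)),
        (b, lambda g: _unbroadcast(g, b.value.shape)),
    ])


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.value - b.value, [
        (a, lambda g: _unbroadcast(g, a.value.shape)),
        (b, lambda g: _unbroadcast(-g, b.value.shape)),
    ])


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.value * b.value, [
        (a, lambda g: _unbroadcast(g * b.value, a.value.shape)),
        (b, lambda g: _unbroadcast(g * a.value, b.value.shape)),
    ])


def div(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.value / b.value, [
        (a, lambda g: _unbroadcast(g / b.value, a.value.shape)),
        (b, lambda g: _unbroadcast(-g * a.value / (b.value ** 2), b.value.shape)),
    ])


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.value, [(a, lambda g: -g)])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """a @ b with a 2-D; b may be 2-D or 1-D (matrix-vector)."""
    out = a.value @ b.value
    if b.value.ndim == 1:
        return Tensor(out, [
            (a, lambda g: np.outer(g, b.value)),
            (b, lambda g: a.value.T @ g),
        ])
    return Tensor(out, [
        (a, lambda g: g @ b.value.T),
        (b, lambda g: a.value.T @ g),
    ])


def transpose(a: Tensor) -> Tensor:
    return Tensor(a.value.T, [(a, lambda g: g.T)])


def reshape(a: Tensor, shape) -> Tensor:
    old = a.value.shape
    return Tensor(a.value.reshape(shape), [(a, lambda g: g.reshape(old))])


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Row selection a[idx]; backward scatter-adds into the source rows."""
    idx = np.asarray(idx)

    def vjp(g):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return out

    return Tensor(a.value[idx], [(a, vjp)])


def segment_sum(a: Tensor, seg: np.ndarray, n: int) -> Tensor:
    """Sum rows of `a` into `n` buckets given by `seg` (scatter-add)."""
    seg = np.asarray(seg)
    out = np.zeros((n,) + a.value.shape[1:], dtype=np.float64)
    np.add.at(out, seg, a.value)
    return Tensor(out, [(a, lambda g: g[seg])])


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.value))
    return Tensor(s, [(a, lambda g: g * s * (1.0 - s))])


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    pos = a.value > 0
    out = np.where(pos, a.value, alpha * np.expm1(a.value))
    return Tensor(out, [(a, lambda g: g * np.where(pos, 1.0, out + alpha))])


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.value)
    return Tensor(e, [(a, lambda g: g * e)])


def sqrt(a: Tensor) -> Tensor:
    r = np.sqrt(a.value)
    return Tensor(r, [(a, lambda g: g * 0.5 / r)])


def power(a: Tensor, p: float) -> Tensor:
    """Elementwise a**p for a constant exponent (base assumed >= 0 for p<1)."""
    return Tensor(a.value ** p, [
        (a, lambda g: g * p * a.value ** (p - 1.0)),
    ])


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.value.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.value.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.value.shape).copy()

    return Tensor(out, [(a, vjp)])


def tmean(a: Tensor) -> Tensor:
    n = a.value.size
    return Tensor(a.value.mean(), [
        (a, lambda g: np.broadcast_to(g / n, a.value.shape).copy()),
    ])
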