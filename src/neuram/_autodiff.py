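"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-free graph implementation: each :class:`Var` records its parents and a
closure that pushes the adjoint back to them.  Only the handful of primitives
needed for small dense networks and their input derivatives is provided
(affine maps, elementwise arithmetic, tanh, reductions).  Gradients with
respect to a leaf used in several places accumulate, which is exactly what the
weight-sharing in the joint encoder/decoder/surrogate loss requires.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "as_var", "grad"]


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Var:
    """Node in the computation graph holding a value and a backward rule."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # --- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_var(other)

        def bwd(g, a=self, b=other):
            a.grad += _unbroadcast(g, a.value.shape)
            b.grad += _unbroadcast(g, b.value.shape)

        return Var(self.value + other.value, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a.grad -= g

        return Var(-self.value, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_var(other))

    def __rsub__(self, other):
        return as_var(other) + (-self)

    def __mul__(self, other):
        other = as_var(other)

        def bwd(g, a=self, b=other):
            a.grad += _unbroadcast(g * b.value, a.value.shape)
            b.grad += _unbroadcast(g * a.value, b.value.shape)

        return Var(self.value * other.value, (self, other), bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = as_var(other)

        def bwd(g, a=self, b=other):
            a.grad += g @ b.value.T
            b.grad += a.value.T @ g

        return Var(self.value @ other.value, (self, other), bwd)

    # --- nonlinearities and reductions -----------------------------------
    def tanh(self):
        out = np.tanh(self.value)

        def bwd(g, a=self, o=out):
            a.grad += g * (1.0 - o * o)

        return Var(out, (self,), bwd)

    def square(self):
        def bwd(g, a=self):
            a.grad += g * 2.0 * a.value

        return Var(self.value**2, (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        val = self.value.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a.grad += np.broadcast_to(gg, a.value.shape)

        return Var(val, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, idx):
        def bwd(g, a=self, i=idx):
            np.add.at(a.grad, i, g)

        return Var(self.value[idx], (self,), bwd)


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def grad(output: Var, leaves: list[Var]) -> list[np.ndarray]:
    """Gradient of a scalar `output` with respect to `leaves`.

    Returns one array per leaf, shaped like the leaf value.
    """
    if output.value.size != 1:
        raise ValueError("grad expects a scalar output")
    # topological order by DFS
    order: list[Var] = []
    seen: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, done = stack.pop()
        if done:
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
    output.grad = np.ones_like(output.value)
    for node in reversed(order):
        if node._backward is not None:
            node._backward(node.grad)
    return [leaf.grad for leaf in leaves]
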