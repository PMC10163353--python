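"""Minimal vectorized reverse-mode automatic differentiation.

The pressure-reconstruction network needs exact derivatives in two directions:

* derivatives of the network *outputs* with respect to its *inputs* (x, y, t),
  which enter the Navier-Stokes residuals — these are propagated forward
  through the layers as extra "channels" (see :mod:`pivpressure.network`);
* derivatives of the training loss with respect to the *parameters*, which
  drive the optimizer — these are obtained by reverse-mode differentiation of
  the taped computation below.

The engine is deliberately small: a :class:`Tensor` wrapping a float64
``numpy`` array, the dozen primitive operations the network and its loss
terms are built from, and a topological-order backward pass.  Broadcasting is
supported in ``+``/``-``/``*`` (gradients are summed over broadcast axes).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape: float64 value, gradient slot, backward rule."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.value.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep seeding d(self)/d(self) = 1 (scalar outputs only)."""
        if self.value.ndim != 0 and self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.value.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.value ** exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.value ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.value.T)
            if other.requires_grad:
                other._accum(self.value.T @ g)

        out._backward = bw
        return out

    def col(self, i: int):
        """Extract column ``i`` of a 2-D tensor as a 1-D tensor."""
        out = Tensor(self.value[:, i], parents=(self,))

        def bw(g):
            if self.requires_grad:
                gg = np.zeros_like(self.value)
                gg[:, i] = g
                self._accum(gg)

        out._backward = bw
        return out

    def square(self):
        return self * self

    def sum(self):
        out = Tensor(self.value.sum(), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.value.shape).copy())

        out._backward = bw
        return out

    def mean(self):
        n = self.value.size
        return self.sum() * (1.0 / n)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.value))
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = bw
    return out


def tanh(x: Tensor) -> Tensor:
    tv = np.tanh(x.value)
    out = Tensor(tv, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * (1.0 - tv * tv))

    out._backward = bw
    return out


def constant(value) -> Tensor:
    return Tensor(value, requires_grad=False)
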