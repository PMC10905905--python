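"""Minimal tape-based reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the graph encoder and the two
training objectives: affine maps, ReLU/PReLU, segment (scatter) sums for
message passing and pooling, row gathering, concatenation, and elementwise
arithmetic with broadcasting. Gradients are accumulated on leaf tensors via
``Tensor.backward()``; correctness is checked against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "prelu", "gather", "segment_sum", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, value, parents, backward) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_val = self.value + other.value

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_val, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_val = self.value * other.value

        def backward(g):
            return (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            )

        return self._make(out_val, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_val = self.value / other.value

        def backward(g):
            return (
                _unbroadcast(g / other.value, self.shape),
                _unbroadcast(-g * self.value / other.value**2, other.shape),
            )

        return self._make(out_val, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_val = self.value @ other.value

        def backward(g):
            return (g @ other.value.T, self.value.T @ g)

        return self._make(out_val, (self, other), backward)

    def square(self):
        return self * self

    def exp(self):
        out_val = np.exp(self.value)
        return self._make(out_val, (self,), lambda g: (g * out_val,))

    def log(self):
        return self._make(np.log(self.value), (self,), lambda g: (g / self.value,))

    def sum(self):
        return self._make(
            np.asarray(self.value.sum()),
            (self,),
            lambda g: (np.broadcast_to(g, self.shape).copy(),),
        )

    def mean(self):
        n = self.value.size
        return self._make(
            np.asarray(self.value.mean()),
            (self,),
            lambda g: (np.broadcast_to(g / n, self.shape).copy(),),
        )

    # -- autodiff driver -------------------------------------------------

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative post-order; molecule tapes can be deep
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.value)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def relu(x: Tensor) -> Tensor:
    mask = x.value > 0
    return x._make(np.where(mask, x.value, 0.0), (x,), lambda g: (g * mask,))


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """PReLU with a single learnable slope (scalar tensor)."""
    mask = x.value > 0
    out_val = np.where(mask, x.value, slope.value * x.value)

    def backward(g):
        gx = g * np.where(mask, 1.0, slope.value)
        gs = _unbroadcast(g * np.where(mask, 0.0, x.value), slope.shape)
        return (gx, gs)

    return x._make(out_val, (x, slope), backward)


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of `x` (gradient scatter-adds back)."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        gx = np.zeros_like(x.value)
        np.add.at(gx, idx, g)
        return (gx,)

    return x._make(x.value[idx], (x,), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `x` into `num_segments` buckets (message aggregation / pooling)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_val = np.zeros((num_segments,) + x.value.shape[1:])
    np.add.at(out_val, segment_ids, x.value)
    return x._make(out_val, (x,), lambda g: (g[segment_ids],))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_val = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_val)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
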