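"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph-network layers, the Adam
training loop and the explainer's mask optimization need: broadcasting
arithmetic, matmul (including stacked/batched), ReLU / LeakyReLU /
sigmoid / exp / log, reductions, concatenation and slicing.  Gradients
are accumulated by a topological backward sweep over the recorded tape.

Usage::

    x = Var(np.ones((3, 2)))
    y = (x @ w).relu().sum()
    y.backward()
    x.grad  # dL/dx
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Var", "concat", "as_var"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the autodiff graph wrapping a float ndarray."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(
        self,
        value: np.ndarray | float,
        parents: tuple["Var", ...] = (),
        backward: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None,
    ):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction helpers -------------------------------------
    def _op(self, value, parents, backward) -> "Var":
        return Var(value, parents, backward)

    def __add__(self, other):
        o = as_var(other)
        return self._op(
            self.value + o.value,
            (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        o = as_var(other)
        return self._op(
            self.value - o.value,
            (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, o.shape)),
        )

    def __rsub__(self, other):
        return as_var(other) - self

    def __mul__(self, other):
        o = as_var(other)
        return self._op(
            self.value * o.value,
            (self, o),
            lambda g: (
                _unbroadcast(g * o.value, self.shape),
                _unbroadcast(g * self.value, o.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_var(other)
        return self._op(
            self.value / o.value,
            (self, o),
            lambda g: (
                _unbroadcast(g / o.value, self.shape),
                _unbroadcast(-g * self.value / o.value**2, o.shape),
            ),
        )

    def __neg__(self):
        return self * -1.0

    def __pow__(self, exponent: float):
        return self._op(
            self.value**exponent,
            (self,),
            lambda g: (g * exponent * self.value ** (exponent - 1),),
        )

    def __matmul__(self, other):
        o = as_var(other)

        def backward(g):
            ga = g @ np.swapaxes(o.value, -1, -2)
            gb = np.swapaxes(self.value, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, o.shape)

        return self._op(self.value @ o.value, (self, o), backward)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.value > 0
        return self._op(self.value * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.value > 0, 1.0, slope)
        return self._op(self.value * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.value, -60, 60)))
        return self._op(s, (self,), lambda g: (g * s * (1 - s),))

    def exp(self):
        e = np.exp(np.clip(self.value, -700, 700))
        return self._op(e, (self,), lambda g: (g * e,))

    def log(self):
        return self._op(np.log(self.value), (self,), lambda g: (g / self.value,))

    def abs(self):
        sign = np.sign(self.value)
        return self._op(np.abs(self.value), (self,), lambda g: (g * sign,))

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._op(self.value.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        return self._op(
            self.value.reshape(shape),
            (self,),
            lambda g: (g.reshape(self.shape),),
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return self._op(
            self.value.transpose(*axes),
            (self,),
            lambda g: (g.transpose(*inv),),
        )

    def __getitem__(self, key):
        def backward(g):
            out = np.zeros(self.shape)
            np.add.at(out, key, g)
            return (out,)

        return self._op(self.value[key], (self,), backward)

    # -- backward sweep ----------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the whole tape."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Var] = []
        seen: set[int] = set()
        stack: list[tuple[Var, bool]] = [(self, False)]
        while stack:  # iterative DFS postorder (graphs can be deep)
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
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad = parent.grad + g


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def concat(vars_: Iterable[Var], axis: int = -1) -> Var:
    """Concatenate Vars along an axis (gradient splits back)."""
    vs = list(vars_)
    sizes = [v.shape[axis] for v in vs]
    value = np.concatenate([v.value for v in vs], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, range(offsets[k], offsets[k + 1]), axis=axis)
            for k in range(len(vs))
        )

    return Var(value, tuple(vs), backward)
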