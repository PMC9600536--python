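"""Minimal reverse-mode automatic differentiation over numpy arrays.

The rule model is a modest computation graph (tens of nodes per
evaluation), so a lightweight tape with full-batch numpy kernels is
ample: every operation records its parents and a closure that
accumulates vector-Jacobian products. Broadcasting follows numpy
semantics; gradients of broadcast operands are summed back to the
operand's shape. Gradients are accumulated lazily (None until touched)
to keep per-node overhead low.

Only the operations the model needs are implemented, plus an escape
hatch (`Tensor(..., parents=..., vjp=...)`) for fused custom nodes with
hand-written gradients. All values are float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln

__all__ = ["Tensor", "as_tensor", "sigmoid", "softplus", "relu", "lgamma", "matmul"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from an operand of `shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: a value, and how to backpropagate."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp", "name")

    def __init__(self, value, requires_grad: bool = False, parents=(), vjp=None,
                 name: str | None = None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._vjp = vjp
        self.name = name

    @property
    def shape(self):
        return self.value.shape

    def accum(self, g) -> None:
        """Add a vector-Jacobian contribution to this node's gradient."""
        if self.grad is None:
            self.grad = g if isinstance(g, np.ndarray) and g.shape == self.shape \
                else np.broadcast_to(g, self.shape).copy()
        else:
            self.grad = self.grad + g

    def accum_b(self, g) -> None:
        """Like accum, but first un-broadcasts g to this node's shape."""
        self.accum(_unbroadcast(np.asarray(g), self.shape))

    def backward(self, grad=None) -> None:
        """Accumulate gradients of self with respect to every reachable leaf."""
        if grad is None:
            if self.value.ndim != 0:
                raise ValueError("backward() without a seed requires a scalar")
            grad = np.ones_like(self.value)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._vjp is not None and node.grad is not None:
                node._vjp(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.value + other.value, parents=(self, other))

            def vjp(g):
                if self.requires_grad:
                    self.accum_b(g)
                if other.requires_grad:
                    other.accum_b(g)
        else:
            out = Tensor(self.value + other, parents=(self,))

            def vjp(g):
                self.accum_b(g)

        out._vjp = vjp
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))
        out._vjp = lambda g: self.accum(-g)
        return out

    def __sub__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.value - other.value, parents=(self, other))

            def vjp(g):
                if self.requires_grad:
                    self.accum_b(g)
                if other.requires_grad:
                    other.accum_b(-g)

            out._vjp = vjp
            return out
        return self + (-other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.value * other.value, parents=(self, other))

            def vjp(g):
                if self.requires_grad:
                    self.accum_b(g * other.value)
                if other.requires_grad:
                    other.accum_b(g * self.value)
        else:
            out = Tensor(self.value * other, parents=(self,))

            def vjp(g):
                self.accum_b(g * other)

        out._vjp = vjp
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.value / other.value, parents=(self, other))

            def vjp(g):
                if self.requires_grad:
                    self.accum_b(g / other.value)
                if other.requires_grad:
                    other.accum_b(-g * self.value / other.value**2)

            out._vjp = vjp
            return out
        return self * (1.0 / other)

    def __rtruediv__(self, other):
        inv = self ** -1.0
        return inv * other

    def __pow__(self, exponent: float):
        out = Tensor(self.value**exponent, parents=(self,))
        out._vjp = lambda g: self.accum(g * exponent * self.value ** (exponent - 1))
        return out

    # -- elementwise functions ---------------------------------------------

    def exp(self):
        val = np.exp(self.value)
        out = Tensor(val, parents=(self,))
        out._vjp = lambda g: self.accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.value), parents=(self,))
        out._vjp = lambda g: self.accum(g / self.value)
        return out

    def sqrt(self):
        val = np.sqrt(self.value)
        out = Tensor(val, parents=(self,))
        out._vjp = lambda g: self.accum(g * 0.5 / val)
        return out

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def vjp(g):
            if axis is None:
                self.accum(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self.accum(np.broadcast_to(g, self.shape))

        out._vjp = vjp
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.value.reshape(shape), parents=(self,))
        out._vjp = lambda g: self.accum(g.reshape(self.shape))
        return out

    def transpose(self, axes=None):
        out = Tensor(self.value.transpose(axes), parents=(self,))

        def vjp(g):
            if axes is None:
                self.accum(g.transpose())
            else:
                self.accum(g.transpose(np.argsort(axes)))

        out._vjp = vjp
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = expit(x.value)
    out = Tensor(val, parents=(x,))
    out._vjp = lambda g: x.accum(g * val * (1.0 - val))
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably; gradient is the logistic function."""
    x = as_tensor(x)
    out = Tensor(np.logaddexp(0.0, x.value), parents=(x,))
    out._vjp = lambda g: x.accum(g * expit(x.value))
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.value, 0.0), parents=(x,))
    out._vjp = lambda g: x.accum(g * (x.value > 0.0))
    return out


def lgamma(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(gammaln(x.value), parents=(x,))
    out._vjp = lambda g: x.accum(g * digamma(x.value))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product with reverse-mode gradients."""
    a, b = as_tensor(a), as_tensor(b)
    if a.value.ndim != 2 or b.value.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    out = Tensor(a.value @ b.value, parents=(a, b))

    def vjp(g):
        if a.requires_grad:
            a.accum(g @ b.value.T)
        if b.requires_grad:
            b.accum(a.value.T @ g)

    out._vjp = vjp
    return out
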