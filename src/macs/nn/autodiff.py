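"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every differentiable operation
returns a :class:`Tensor` holding the result, its parents and a closure
that accumulates gradients into the parents.  ``Tensor.backward()`` runs
the closures in reverse topological order.  All arithmetic is float32 by
default; loss reductions accumulate in float64 so analytic checkpoints
(ln 2, -p ln p values, ...) hold to ~1e-7.

The engine is single-threaded, deterministic and CPU-only by design —
experiments at desk scale (64x64 images, channel widths of a few tens)
run in seconds to minutes and reproduce bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate_grad(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=DTYPE)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ------------------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def _bwd(g):
            if self.requires_grad or self._parents:
                self.accumulate_grad(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other.accumulate_grad(_unbroadcast(g, other.data.shape))

        out._backward = _bwd
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def _bwd(g):
            if self.requires_grad or self._parents:
                self.accumulate_grad(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other.accumulate_grad(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bwd
        return out

    def __neg__(self):
        return self * Tensor(np.asarray(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(dtype=np.float64), True, (self,))

        def _bwd(g):
            self.accumulate_grad(np.broadcast_to(g, self.data.shape))

        out._backward = _bwd
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(dtype=np.float64), True, (self,))

        def _bwd(g):
            self.accumulate_grad(np.broadcast_to(g / n, self.data.shape))

        out._backward = _bwd
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _bwd(g):
            self.accumulate_grad(g.reshape(self.data.shape))

        out._backward = _bwd
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"
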