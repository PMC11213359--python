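"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains a conditional normalizing flow jointly with a recurrent
summary network, which requires gradients of a scalar loss with respect to
every network weight, including the path through the conditioning vector.
This module provides exactly the operations those networks need (affine maps,
pointwise nonlinearities, concatenation, gathering, reductions), recorded on
a dynamic tape and differentiated by reverse accumulation.

All values are float64 ndarrays.  Gradients of a node are accumulated into
``node.grad`` once :meth:`Tensor.backward` is called on a scalar output.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_cols",
    "check_gradients",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("v", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, value, requires_grad: bool = False):
        self.v = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._bw = None  # callable(out_grad) applied during backward

    # ---- graph construction -------------------------------------------------

    @classmethod
    def _node(cls, value, parents, bw):
        t = cls(value)
        if any(p.requires_grad for p in parents):
            t.requires_grad = True
            t._parents = tuple(parents)
            t._bw = bw
        return t

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.v.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    @property
    def shape(self):
        return self.v.shape

    # ---- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._node(self.v + other.v, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._node(-self.v, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(-g)

        return Tensor._node(self.v - other.v, (self, other), bw)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.v)
            if other.requires_grad:
                other._accum(g * self.v)

        return Tensor._node(self.v * other.v, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other: "Tensor"):
        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.v.T)
            if other.requires_grad:
                other._accum(self.v.T @ g)

        return Tensor._node(self.v @ other.v, (self, other), bw)

    # ---- nonlinearities -----------------------------------------------------

    def exp(self):
        out_v = np.exp(self.v)

        def bw(g):
            self._accum(g * out_v)

        return Tensor._node(out_v, (self,), bw)

    def tanh(self):
        out_v = np.tanh(self.v)

        def bw(g):
            self._accum(g * (1.0 - out_v * out_v))

        return Tensor._node(out_v, (self,), bw)

    def sigmoid(self):
        out_v = 1.0 / (1.0 + np.exp(-self.v))

        def bw(g):
            self._accum(g * out_v * (1.0 - out_v))

        return Tensor._node(out_v, (self,), bw)

    def elu(self):
        """Exponential linear unit: x for x>0, exp(x)-1 otherwise."""
        pos = self.v > 0
        out_v = np.where(pos, self.v, np.expm1(self.v))

        def bw(g):
            self._accum(g * np.where(pos, 1.0, out_v + 1.0))

        return Tensor._node(out_v, (self,), bw)

    def soft_clamp(self, alpha: float):
        """Smoothly bound values to (-alpha, alpha) via (2a/pi)*arctan(x/a).

        Used on the log-scale outputs of coupling layers so that exp() of
        them stays in a numerically safe range.
        """
        a = float(alpha)
        out_v = (2.0 * a / np.pi) * np.arctan(self.v / a)

        def bw(g):
            self._accum(g * (2.0 / np.pi) / (1.0 + (self.v / a) ** 2))

        return Tensor._node(out_v, (self,), bw)

    # ---- reductions and shaping ---------------------------------------------

    def sum(self, axis=None):
        out_v = self.v.sum(axis=axis)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.v.shape))
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.v.shape))

        return Tensor._node(out_v, (self,), bw)

    def mean(self, axis=None):
        n = self.v.size if axis is None else self.v.shape[axis]
        return self.sum(axis=axis) / n

    def slice_cols(self, lo: int, hi: int):
        """Columns [lo, hi) of a 2-D tensor."""

        def bw(g):
            full = np.zeros_like(self.v)
            full[:, lo:hi] = g
            self._accum(full)

        return Tensor._node(self.v[:, lo:hi], (self,), bw)

    # ---- backward -----------------------------------------------------------

    def backward(self):
        if self.v.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.v)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate 2-D tensors along ``axis`` (only axis=1 is needed/supported)."""
    if axis != 1:
        raise NotImplementedError("only axis=1 concatenation is supported")
    widths = [t.v.shape[1] for t in tensors]
    offsets = np.cumsum([0] + widths)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(g[:, lo:hi])

    return Tensor._node(np.concatenate([t.v for t in tensors], axis=1), tuple(tensors), bw)


def gather_cols(t: Tensor, idx: np.ndarray) -> Tensor:
    """Permute/gather columns of a 2-D tensor: out[:, j] = t[:, idx[j]]."""
    idx = np.asarray(idx, dtype=np.intp)

    def bw(g):
        full = np.zeros_like(t.v)
        np.add.at(full, (slice(None), idx), g)
        t._accum(full)

    return Tensor._node(t.v[:, idx], (t,), bw)


def check_gradients(fn, params: list[Tensor], eps: float = 1e-6) -> float:
    """Max relative error between analytic and central-difference gradients.

    ``fn()`` must rebuild the graph from ``params`` and return a scalar Tensor.
    Intended for tests and debugging of new network components.
    """
    out = fn()
    for p in params:
        p.grad = None
    out.backward()
    analytic = [p.grad.copy() if p.grad is not None else np.zeros_like(p.v) for p in params]
    worst = 0.0
    for p, g in zip(params, analytic):
        flat = p.v.ravel()
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            f_plus = float(fn().v)
            flat[i] = orig - eps
            f_minus = float(fn().v)
            flat[i] = orig
            num[i] = (f_plus - f_minus) / (2 * eps)
        denom = np.maximum(np.abs(num), np.abs(g.ravel()))
        denom[denom < 1e-8] = 1.0
        worst = max(worst, float(np.max(np.abs(num - g.ravel()) / denom)))
    return worst
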