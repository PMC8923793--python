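"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it; :meth:`Tensor.backward` accumulates gradients through the tape.
Only the operations needed by the sequence models in this package are
implemented (broadcast arithmetic, matmul, pointwise nonlinearities,
reductions, log-sum-exp, concatenation/stacking and numpy-style indexing).
Gradient correctness is guarded by finite-difference tests.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        if not _track(self, other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        if not _track(self, other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor(out_data, True, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)
        if not _track(self, other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    # -- pointwise -----------------------------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor(out_data, True, (self,), bwd)

    def sigmoid(self):
        out_data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, True, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor(out_data, True, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            self._accum(g / self.data)

        return Tensor(out_data, True, (self,), bwd)

    def softplus(self):
        """log(1 + exp(x)), computed stably."""
        out_data = np.logaddexp(0.0, self.data)
        if not _track(self):
            return Tensor(out_data)
        sig = 0.5 * (np.tanh(0.5 * self.data) + 1.0)

        def bwd(g):
            self._accum(g * sig)

        return Tensor(out_data, True, (self,), bwd)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, True, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = np.exp(self.data - m)
        s = shifted.sum(axis=axis, keepdims=True)
        out_k = m + np.log(s)
        out_data = out_k if keepdims else np.squeeze(out_k, axis=axis)
        if not _track(self):
            return Tensor(out_data)
        soft = shifted / s  # softmax along axis

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * soft)

        return Tensor(out_data, True, (self,), bwd)

    # -- shape ---------------------------------------------------------------

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor(out_data, True, (self,), bwd)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor(out_data, True, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(out_data, True, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*tensors: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad for t in tensors)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    if not _track(*ts):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, True, tuple(ts), bwd)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in ts], axis=axis)
    if not _track(*ts):
        return Tensor(out_data)

    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(ts, parts):
            if t.requires_grad:
                t._accum(gp)

    return Tensor(out_data, True, tuple(ts), bwd)


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``table[indices]`` with scatter-add gradient."""
    idx = np.asarray(indices)
    out_data = table.data[idx]
    if not _track(table):
        return Tensor(out_data)

    def bwd(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        table._accum(full)

    return Tensor(out_data, True, (table,), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or ``p == 0``."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
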