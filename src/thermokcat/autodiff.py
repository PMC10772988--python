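"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the kcat model needs: broadcast-aware
elementwise arithmetic, (batched) matrix products, leaky ReLU / tanh,
masked softmax, concatenation, reductions, embedding lookup and a
zero-padded sequence shift (the building block of same-padded 1-D
convolutions).  Gradients are accumulated by topological traversal of the
recorded operation graph.  A module-level switch (`no_grad`) disables graph
recording for inference.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out.requires_grad = track
        out._backward = backward if track else None
        out._parents = tuple(parents) if track else ()
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS (deep graphs exceed recursion limits)
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def square(self):
        return self * self

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __matmul__ = matmul

    def swapaxes(self, a: int, b: int) -> "Tensor":
        data = np.swapaxes(self.data, a, b)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(data, (self,), backward)

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape
        data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(data, (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def leaky_relu(self, slope: float = 0.1) -> "Tensor":
        pos = self.data > 0
        data = np.where(pos, self.data, slope * self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.where(pos, g, slope * g))

        return Tensor._make(data, (self,), backward)

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - data * data))

        return Tensor._make(data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                else:
                    ge = g if keepdims else np.expand_dims(g, axis)
                    self._accumulate(np.broadcast_to(ge, self.data.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structured ops -----------------------------------------------------
    def expand_last(self) -> "Tensor":
        """Append a trailing axis of length 1 (for weighted sums)."""
        return self.reshape(*self.data.shape, 1)


def masked_softmax(logits: Tensor, mask: np.ndarray | None = None, axis: int = -1) -> Tensor:
    """Softmax over `axis`; positions where mask==0 receive zero probability.

    `mask` is a plain array broadcastable to `logits` with 1 at valid
    positions. Rows that are entirely masked are not supported.
    """
    x = logits.data
    if mask is not None:
        x = np.where(mask > 0, x, -np.inf)
    x = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(x)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if logits.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            logits._accumulate(y * (g - dot))

    return Tensor._make(y, (logits,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(data, tuple(tensors), backward)


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup `table[indices]` with scatter-add gradient."""
    idx = np.asarray(indices, dtype=np.intp)
    data = table.data[idx]

    def backward(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accumulate(gt)

    return Tensor._make(data, (table,), backward)


def shift(x: Tensor, offset: int, axis: int = 1) -> Tensor:
    """Shift along `axis` by `offset`, filling vacated positions with zeros.

    offset>0 moves entries toward higher indices (out[i] = x[i-offset]).
    """
    if offset == 0:
        return x
    data = np.zeros_like(x.data)
    n = x.data.shape[axis]
    src = [slice(None)] * x.data.ndim
    dst = [slice(None)] * x.data.ndim
    if offset > 0:
        dst[axis] = slice(offset, n)
        src[axis] = slice(0, n - offset)
    else:
        dst[axis] = slice(0, n + offset)
        src[axis] = slice(-offset, n)
    data[tuple(dst)] = x.data[tuple(src)]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(g)
            gx[tuple(src)] = g[tuple(dst)]
            x._accumulate(gx)

    return Tensor._make(data, (x,), backward)


# -- parameter initialisation & optimiser ------------------------------------

def xavier_uniform(shape: tuple[int, ...], rng: np.random.Generator) -> Tensor:
    """Glorot-style uniform initialisation; fan computed from the two last axes."""
    if len(shape) == 1:
        fan_in = fan_out = shape[0]
    else:
        fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class Adam:
    """Adam optimiser over a name->Tensor parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
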