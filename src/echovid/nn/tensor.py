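"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Everything is float32. The graph is built eagerly by the free functions /
operator overloads below; :meth:`Tensor.backward` runs a topological sweep.
Only the primitives needed by the models in this package are implemented.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "concatenate",
    "pad",
    "softmax",
    "log_softmax",
    "gelu",
    "relu",
    "tanh",
    "sigmoid",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autograd ------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _ensure(other)
        out = _make(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _ensure(other)
        out = _make(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_ensure(other))

    def __rsub__(self, other):
        return _ensure(other) + (-self)

    def __truediv__(self, other):
        other = _ensure(other)
        return self * (other ** -1.0)

    def __rtruediv__(self, other):
        return _ensure(other) * (self ** -1.0)

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _ensure(other)
        out = _make(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape surgery -------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice, type(None), type(Ellipsis)))
                    for p in parts)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:  # no repeated elements possible -> plain assignment
                    full[idx] = g
                else:
                    np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bw
        return out

    # -- elementwise ---------------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = bw
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    req = any(p.requires_grad for p in parents)
    t = Tensor(data, requires_grad=req)
    if req:
        t._parents = tuple(parents)
    return t


# ---------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------

def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accumulate(g[tuple(sl)])
            start += s

    out._backward = bw
    return out


def pad(t: Tensor, widths) -> Tensor:
    """Zero-pad; `widths` as for np.pad (per-axis (before, after))."""
    out = _make(np.pad(t.data, widths), (t,))

    def bw(g):
        if t.requires_grad:
            sl = tuple(slice(b, g.shape[i] - a) for i, (b, a) in enumerate(widths))
            t._accumulate(g[sl])

    out._backward = bw
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    m = t.data.max(axis=axis, keepdims=True)
    e = np.exp(t.data - m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (t,))

    def bw(g):
        if t.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            t._accumulate(s * (g - dot))

    out._backward = bw
    return out


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    m = t.data.max(axis=axis, keepdims=True)
    z = t.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    ls = z - lse
    out = _make(ls, (t,))
    s = np.exp(ls)

    def bw(g):
        if t.requires_grad:
            t._accumulate(g - s * g.sum(axis=axis, keepdims=True))

    out._backward = bw
    return out


def relu(t: Tensor) -> Tensor:
    mask = (t.data > 0).astype(np.float32)
    out = _make(t.data * mask, (t,))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g * mask)

    out._backward = bw
    return out


def gelu(t: Tensor) -> Tensor:
    """Exact (erf) GELU."""
    x = t.data
    cdf = 0.5 * (1.0 + _erf(x / np.sqrt(2.0))).astype(np.float32)
    out = _make(x * cdf, (t,))
    pdf = (np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)).astype(np.float32)

    def bw(g):
        if t.requires_grad:
            t._accumulate(g * (cdf + x * pdf))

    out._backward = bw
    return out


def tanh(t: Tensor) -> Tensor:
    y = np.tanh(t.data)
    out = _make(y, (t,))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g * (1.0 - y * y))

    out._backward = bw
    return out


def sigmoid(t: Tensor) -> Tensor:
    x = t.data
    y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out = _make(y.astype(np.float32), (t,))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g * y * (1.0 - y))

    out._backward = bw
    return out
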