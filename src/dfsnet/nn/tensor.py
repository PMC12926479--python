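"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: every operation returns a new
:class:`Tensor` holding the result plus a closure that routes the upstream
gradient to its inputs.  ``backward()`` walks the graph in reverse
topological order.  Only what the detector needs is implemented; dtype is
preserved (float32 by default, float64 when the caller supplies it), which
lets numerical tests run in double precision.
"""

from __future__ import annotations

import contextlib

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concatenate",
    "stack",
    "where",
    "maximum",
    "minimum",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x, like: np.ndarray | None = None) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x
    dtype = like.dtype if like is not None else np.float32
    return np.asarray(x, dtype=dtype)


class Tensor:
    """An n-d array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        if isinstance(data, (np.ndarray, np.generic)):
            data = np.asarray(data)
            if data.dtype not in (np.float32, np.float64):
                data = data.astype(np.float32)
        else:
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple, backward) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def __len__(self) -> int:
        return len(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data + other.data

        def backward(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data - other.data

        def backward(g):
            self._accum(g)
            other._accum(-g)

        return Tensor._make(out_data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor(_as_array(other, self.data)) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data * other.data

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data / other.data

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(_as_array(other, self.data)) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            if b.ndim >= 2:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
            else:  # matrix @ vector
                ga = g[..., None] * b
            if a.ndim >= 2:
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
            else:
                gb = a[..., None] * g
            self._accum(ga)
            other._accum(gb)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        # exact form: x * Phi(x)
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = x * phi

        def backward(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            self._accum(g * (phi + x * pdf))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1+exp(x))
        x = self.data
        out_data = np.logaddexp(0.0, x)

        def backward(g):
            self._accum(g / (1.0 + np.exp(-x)))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        x = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(src_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def pad2d(self, left: int, right: int, top: int, bottom: int, value: float = 0.0):
        """Pad the trailing two (spatial) axes of an N-d tensor."""
        if min(left, right, top, bottom) < 0:
            raise ValueError("padding amounts must be non-negative")
        pad = [(0, 0)] * (self.data.ndim - 2) + [(top, bottom), (left, right)]
        out_data = np.pad(self.data, pad, constant_values=value)
        h, w = self.data.shape[-2:]

        def backward(g):
            sl = (Ellipsis, slice(top, top + h), slice(left, left + w))
            self._accum(g[sl])

        return Tensor._make(out_data, (self,), backward)

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph as we go
                if node is not self:
                    node._backward = None


# -- free functions -----------------------------------------------------------

def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def where(cond: np.ndarray, a, b) -> Tensor:
    """Differentiable selection; ``cond`` is a plain boolean array."""
    a = a if isinstance(a, Tensor) else Tensor(np.asarray(a))
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b))
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        a._accum(g * cond)
        b._accum(g * (~cond))

    return Tensor._make(out_data, (a, b), backward)


def maximum(a, b) -> Tensor:
    """Elementwise max; at ties the gradient goes to the first argument."""
    a = a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64 if isinstance(b, Tensor) and b.dtype == np.float64 else np.float32))
    b = b if isinstance(b, Tensor) else Tensor(_as_array(b, a.data))
    return where(a.data >= b.data, a, b)


def minimum(a, b) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64 if isinstance(b, Tensor) and b.dtype == np.float64 else np.float32))
    b = b if isinstance(b, Tensor) else Tensor(_as_array(b, a.data))
    return where(a.data <= b.data, a, b)
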