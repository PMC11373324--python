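"""Small reverse-mode automatic differentiation engine on NumPy arrays.

This is the numerical core of the package: a tape-based ``Tensor`` holding a
float64 ndarray, a gradient buffer, and a closure that propagates gradients to
its parents.  The op set is exactly what the molecular encoders and the
contrastive objective need — broadcast arithmetic, (batched) matmul, softmax,
reductions, gather/embedding lookup, concatenation — nothing more.  Everything
runs in double precision: molecules here are tiny (tens of atoms) and exact,
checkable numerics are worth more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- introspection --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> np.ndarray:
        return self.data.copy()

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(out):
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(out):
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data / other.data

        def backward(out):
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)
        out_data = self.data**exponent

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(out):
            g = out.grad
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                if self.requires_grad:
                    self._accum(g @ b.T)
                if other.requires_grad:
                    other._accum(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 1:
                if self.requires_grad:
                    self._accum(np.outer(g, b))
                if other.requires_grad:
                    other._accum(a.T @ g)
            else:
                if self.requires_grad:
                    ga = g @ np.swapaxes(b, -1, -2)
                    self._accum(_unbroadcast(ga, a.shape))
                if other.requires_grad:
                    gb = np.swapaxes(a, -1, -2) @ g
                    other._accum(_unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * out.data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data**2))

        return self._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + e^x), computed stably via logaddexp."""
        out_data = np.logaddexp(self.data, 0.0)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad / (1.0 + np.exp(-self.data)))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(out):
            if self.requires_grad:
                g = out.grad
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        return self._make(s, (self,), backward)

    # -- reductions and shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(out):
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, shape):
        out_data = self.data.reshape(shape)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(out):
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        return self._make(out_data, (self,), backward)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        return self._make(out_data, (self,), backward)

    def take_rows(self, indices):
        """Gather rows (embedding lookup); gradients scatter-add back."""
        idx = np.asarray(indices, dtype=np.intp)
        out_data = self.data[idx]

        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        return self._make(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        g = np.moveaxis(out.grad, axis, 0)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(np.moveaxis(g[lo:hi], 0, axis))

    probe = tensors[0]
    return probe._make(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(out):
        g = np.moveaxis(out.grad, axis, 0)
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(g[i])

    probe = tensors[0]
    return probe._make(out_data, tuple(tensors), backward)
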