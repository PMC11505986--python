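"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the survival losses and multilayer
perceptrons need: broadcast arithmetic, matmul, exp/log/softplus/sigmoid,
relu, cumulative and reduced sums, and fancy indexing (gather).  Gradients
are accumulated by a topological backward sweep, micrograd-style, but on
whole ndarrays rather than scalars.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make `ndarray <op> Tensor` defer to the Tensor reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)
        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    # ---- elementwise nonlinearities ------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            self._accum(g * out_data)
        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g):
            self._accum(g * mask)
        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = _sigmoid(self.data)
        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))
        return self._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), overflow-safe; gradient is sigmoid(x)."""
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        def backward(g):
            self._accum(g * _sigmoid(self.data))
        return self._make(out_data, (self,), backward)

    # ---- reductions / structure ----------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def cumsum(self, axis=-1):
        def backward(g):
            self._accum(np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis))
        return self._make(np.cumsum(self.data, axis=axis), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        return self._make(self.data[idx], (self,), backward)

    def reshape(self, *shape):
        orig = self.data.shape
        def backward(g):
            self._accum(g.reshape(orig))
        return self._make(self.data.reshape(*shape), (self,), backward)

    # ---- numerically convenient composites ------------------------------

    def logsumexp(self, axis=-1, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)  # detached shift (shift-invariant)
        shifted = self - m
        return shifted.exp().sum(axis=axis, keepdims=keepdims).log() + (
            m if keepdims else np.squeeze(m, axis=axis)
        )

    def softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        e = (self - m).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
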