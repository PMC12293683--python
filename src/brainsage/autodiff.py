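"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Exactly the operator set the graph networks in this package need: broadcast
arithmetic, matrix products (with leading batch dimensions), axis
reductions, leaky ReLU, softmax, concatenation and shape moves. Gradients
are accumulated by a topological-order sweep over the tape; broadcast
gradients are summed back to the parent's shape.

This is deliberately small and dependency-free — it is an implementation
vehicle for the fixed architectures in :mod:`brainsage.model`, not a
general-purpose framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "concat", "stack", "mse"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------
    def _make(self, data, parents, backward):
        return Tensor(data, parents=parents, backward=backward)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    def __sub__(self, other):
        other = _as_tensor(other)
        out_data = self.data - other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return self._make(out_data, (self, other), backward)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            )

        return self._make(out_data, (a, b), backward)

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    __radd__ = __add__
    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make(out_data, (a, b), backward)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        out_data = self.data.mean(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape) / count,)

        return self._make(out_data, (self,), backward)

    def max(self, axis):
        out_data = self.data.max(axis=axis)
        # ties broadcast gradient equally — measure-zero event for our use
        mask = self.data == np.expand_dims(out_data, axis)
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def backward(g):
            return (np.expand_dims(g, axis) * mask,)

        return self._make(out_data, (self,), backward)

    # ---- nonlinearities --------------------------------------------------
    def leaky_relu(self, slope=0.01):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g):
            return (g * factor,)

        return self._make(self.data * factor, (self,), backward)

    def softmax(self, axis):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return self._make(s, (self,), backward)

    # ---- shape moves -----------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            return (np.transpose(g, inv),)

        return self._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, key):
        shape = self.shape

        def backward(g):
            full = np.zeros(shape)
            np.add.at(full, key, g)
            return (full,)

        return self._make(self.data[key], (self,), backward)

    # ---- backward sweep --------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if p.requires_grad:
                    p.grad = p.grad + g if p.grad is not None else g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=float), requires_grad=True)


def concat(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), backward=backward)


def stack(tensors, axis=0) -> Tensor:
    out = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor(out, parents=tuple(tensors), backward=backward)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - constant(target)
    return (diff * diff).mean()
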