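"""Minimal vectorized reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients into every tensor created with ``requires_grad=True``.
Only the operations needed by the condition-generation networks are provided.
All arithmetic supports NumPy broadcasting; gradients of broadcast operands
are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # --- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def bw(g):
            return (g * p * np.power(self.data, p - 1),)

        return self._make(np.power(self.data, p), (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def bw(g):
            g = np.asarray(g)
            if a.ndim == 2 and b.ndim == 2:
                ga, gb = g @ b.T, a.T @ g
            elif a.ndim == 1 and b.ndim == 2:
                ga, gb = g @ b.T, np.outer(a, g)
            elif a.ndim == 2 and b.ndim == 1:
                ga, gb = np.outer(g, b), a.T @ g
            else:  # vector dot product
                ga, gb = g * b, g * a
            return (ga, gb)

        return self._make(a @ b, (self, other), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(self.data[idx], (self,), bw)

    # --- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            return (g * out_data,)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            return (g * (1.0 - out_data**2),)

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g):
            return (g * out_data * (1.0 - out_data),)

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), bw)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            return (g / (1.0 + np.exp(-self.data)),)

        return self._make(out_data, (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            return (g * sign,)

        return self._make(np.abs(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            return (g * mask,)

        return self._make(np.clip(self.data, lo, hi), (self,), bw)

    # --- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cumsum(self, axis: int = -1):
        def bw(g):
            return (np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis),)

        return self._make(np.cumsum(self.data, axis=axis), (self,), bw)

    def reshape(self, *shape):
        def bw(g):
            return (g.reshape(self.shape),)

        return self._make(self.data.reshape(*shape), (self,), bw)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bw(g):
            expanded = out_data if keepdims or axis is None else np.expand_dims(out_data, axis)
            mask = self.data == expanded
            mask = mask / mask.sum(axis=axis, keepdims=True)
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (mask * g,)

        return self._make(out_data, (self,), bw)

    # --- composites -----------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(()))

    # --- backward pass ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg
            if node is self or not node._parents:
                node.grad = g if node.grad is None else node.grad + g


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            return tuple(
                np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
                for i in range(len(tensors))
            )

        out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def bw(g):
            return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

        out._backward = bw
    return out
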