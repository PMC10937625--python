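"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for the mapper network: dense/batched matmul,
elementwise arithmetic, softmax, layer norm, gather, and a scalar loss.
Constants may be plain ndarrays; only :class:`Tensor` operands accumulate
gradients.  The graph is rebuilt on every forward pass.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "gather_pairs", "softmax", "layer_norm"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # --- graph construction ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # --- arithmetic --------------------------------------------------------
    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, s in enumerate(shape):
            if s == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g

    def __add__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(Tensor._unbroadcast(g, self.data.shape))
            if other_t.requires_grad:
                other_t._accumulate(Tensor._unbroadcast(g, other_t.data.shape))

        return Tensor._make(self.data + other_t.data, (self, other_t), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(Tensor._unbroadcast(g * other_t.data, self.data.shape))
            if other_t.requires_grad:
                other_t._accumulate(Tensor._unbroadcast(g * self.data, other_t.data.shape))

        return Tensor._make(self.data * other_t.data, (self, other_t), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other_t * (-1.0))

    def __matmul__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other_t.data, -1, -2)
                self._accumulate(Tensor._unbroadcast(ga, self.data.shape))
            if other_t.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other_t._accumulate(Tensor._unbroadcast(gb, other_t.data.shape))

        return Tensor._make(self.data @ other_t.data, (self, other_t), backward)

    # --- unary -------------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accumulate(g * y * (1.0 - y))

        return Tensor._make(y, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            self._accumulate(np.full_like(self.data, float(g) / n))

        return Tensor._make(self.data.mean(), (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(*inv))

        return Tensor._make(self.data.transpose(*axes), (self,), backward)

    def swap_last(self):
        def backward(g):
            self._accumulate(np.swapaxes(g, -1, -2))

        return Tensor._make(np.swapaxes(self.data, -1, -2), (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    index = np.asarray(index, dtype=np.intp)

    def backward(g):
        acc = np.zeros_like(t.data)
        np.add.at(acc, index, g)
        t._accumulate(acc)

    return Tensor._make(t.data[index], (t,), backward)


def gather_pairs(t: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)

    def backward(g):
        acc = np.zeros_like(t.data)
        np.add.at(acc, (rows, cols), g)
        t._accumulate(acc)

    return Tensor._make(t.data[rows, cols], (t,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        t._accumulate(y * (g - dot))

    return Tensor._make(y, (t,), backward)


def layer_norm(t: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = t.data.mean(axis=-1, keepdims=True)
    xc = t.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(
                Tensor._unbroadcast(g * xhat, gamma.data.shape)
            )
        if beta.requires_grad:
            beta._accumulate(Tensor._unbroadcast(g, beta.data.shape))
        if t.requires_grad:
            gx = g * gamma.data
            n = t.data.shape[-1]
            dx = (
                gx
                - gx.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            t._accumulate(dx)

    return Tensor._make(xhat * gamma.data + beta.data, (t, gamma, beta), backward)
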