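"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough tensor machinery to express the cell-graph network and its
ranking loss: dense affine maps, ReLU/sigmoid, concatenation, row gather
and segment means (for neighbourhood aggregation), and reductions.
Gradients are accumulated by reverse topological traversal of the tape.
Correctness is property-tested against finite differences.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "relu", "sigmoid", "softplus", "concat", "gather",
           "segment_sum", "matmul", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- ops ---------------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        def backward(g):
            self._accumulate(g)
            other._accumulate(g)
        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        def backward(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    def sum(self) -> "Tensor":
        def backward(g):
            self._accumulate(np.full_like(self.data, float(g)))
        return Tensor._make(self.data.sum(), (self,), backward)

    def mean_axis0(self) -> "Tensor":
        n = self.data.shape[0]
        def backward(g):
            self._accumulate(np.broadcast_to(g / n, self.data.shape))
        return Tensor._make(self.data.mean(axis=0, keepdims=True),
                            (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size
        def backward(g):
            self._accumulate(np.full_like(self.data, float(g) / n))
        return Tensor._make(self.data.mean(), (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        def backward(g):
            self._accumulate(g.reshape(old))
        return Tensor._make(self.data.reshape(*shape), (self,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    def backward(g):
        x._accumulate(g * mask)
    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    def backward(g):
        x._accumulate(g * s * (1.0 - s))
    return Tensor._make(s, (x,), backward)


def softplus(x: Tensor) -> Tensor:
    # numerically stable log(1 + e^x)
    s = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    def backward(g):
        x._accumulate(g * sig)
    return Tensor._make(s, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of a matrix; backward scatters gradient rows back."""
    index = np.asarray(index, dtype=np.int64)
    def backward(g):
        out = np.zeros_like(x.data)
        np.add.at(out, index, g)
        x._accumulate(out)
    return Tensor._make(x.data[index], (x,), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray,
                num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets (scatter-add)."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out_data = np.zeros((num_segments, x.data.shape[1]))
    np.add.at(out_data, segment_ids, x.data)
    def backward(g):
        x._accumulate(g[segment_ids])
    return Tensor._make(out_data, (x,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._coerce(a) @ b


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
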