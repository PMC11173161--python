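"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core under every trainable component in the package
(graph attention layers, pooling, the energy network). It implements only
the operations those layers need — elementwise arithmetic, matmul,
reductions, gather/scatter for message passing, concatenation and reshape —
with float64 arrays throughout. Gradients are validated against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: Array | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd engine ------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor without grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = grad.astype(np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))

        def bwd(g: Array) -> None:
            self._accumulate(-g)
        out._backward = bwd if out.requires_grad else None
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g: Array) -> None:
            self._accumulate(g * p * self.data ** (p - 1.0))
        out._backward = bwd if out.requires_grad else None
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))

        def bwd(g: Array) -> None:
            self._accumulate(g * out.data)
        out._backward = bwd if out.requires_grad else None
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g: Array) -> None:
            self._accumulate(g / self.data)
        out._backward = bwd if out.requires_grad else None
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g: Array) -> None:
            self._accumulate(g * (self.data > 0.0))
        out._backward = bwd if out.requires_grad else None
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), parents=(self,))

        def bwd(g: Array) -> None:
            self._accumulate(g * (1.0 - out.data ** 2))
        out._backward = bwd if out.requires_grad else None
        return out

    def sigmoid(self) -> "Tensor":
        sd = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(sd, parents=(self,))

        def bwd(g: Array) -> None:
            self._accumulate(g * sd * (1.0 - sd))
        out._backward = bwd if out.requires_grad else None
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), parents=(self,))

        def bwd(g: Array) -> None:
            self._accumulate(g * np.sign(self.data))
        out._backward = bwd if out.requires_grad else None
        return out

    # -- linear algebra, reductions, shaping ----------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor.as_tensor(other)
        if self.ndim != 2 or other.ndim != 2:
            raise ValueError("matmul supports 2-D tensors only")
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        out._backward = bwd if out.requires_grad else None
        return out

    __matmul__ = matmul

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g: Array) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(ge, self.data.shape).copy())
        out._backward = bwd if out.requires_grad else None
        return out

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g: Array) -> None:
            self._accumulate(g.reshape(self.data.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    def gather(self, index: Array) -> "Tensor":
        """Row selection along the first axis (with repetition)."""
        index = np.asarray(index, dtype=int)
        out = Tensor(self.data[index], parents=(self,))

        def bwd(g: Array) -> None:
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            self._accumulate(acc)
        out._backward = bwd if out.requires_grad else None
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g: Array) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = bwd if out.requires_grad else None
    return out


def segment_sum(x: Tensor, segment_ids: Array, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets along the first axis."""
    segment_ids = np.asarray(segment_ids, dtype=int)
    shape = (n_segments,) + x.data.shape[1:]
    data = np.zeros(shape)
    np.add.at(data, segment_ids, x.data)
    out = Tensor(data, parents=(x,))

    def bwd(g: Array) -> None:
        x._accumulate(g[segment_ids])
    out._backward = bwd if out.requires_grad else None
    return out


def segment_mean(x: Tensor, segment_ids: Array, n_segments: int) -> Tensor:
    """Mean per segment; empty segments yield zero rows."""
    counts = np.bincount(np.asarray(segment_ids, dtype=int), minlength=n_segments)
    counts = np.maximum(counts, 1).astype(float)
    s = segment_sum(x, segment_ids, n_segments)
    inv = (1.0 / counts).reshape((n_segments,) + (1,) * (x.data.ndim - 1))
    return s * inv


def segment_softmax(logits: Tensor, segment_ids: Array, n_segments: int) -> Tensor:
    """Softmax of ``logits`` within each segment (first axis grouping).

    The per-segment max is subtracted as a constant for numerical
    stability; its gradient contribution cancels exactly in the softmax.
    """
    segment_ids = np.asarray(segment_ids, dtype=int)
    m = np.full((n_segments,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(m, segment_ids, logits.data)
    z = (logits - m[segment_ids]).exp()
    denom = segment_sum(z, segment_ids, n_segments)
    return z * denom.gather(segment_ids).pow(-1.0)


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack scalar/1-row tensors into a single column vector."""
    cols = [t.reshape(1, -1) for t in tensors]
    return concat(cols, axis=0)
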