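"""Reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (proteins of a few hundred residues,
feature widths of order 10^2), so a thin define-by-run tape over numpy is
sufficient: every operation records its parents and a closure that pushes the
upstream gradient back to them, and :meth:`Tensor.backward` walks the tape in
reverse topological order.

Only the operations the model needs are provided.  Two graph-specific
primitives, :func:`segment_sum` and :func:`segment_softmax`, support
neighbourhood aggregation and per-neighbourhood attention normalisation
without materialising dense adjacency structure.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack_rows",
    "const_matmul",
    "segment_sum",
    "segment_softmax",
    "softmax",
    "sigmoid",
    "relu",
    "leaky_relu",
    "silu",
    "tanh",
    "exp",
    "log",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to Tensor's reflected operators (ndarray op Tensor)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _from_op(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        live = tuple(p for p in parents if p.requires_grad or p._parents)
        if live:
            out.requires_grad = True
            out._parents = live
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- tape walk ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(g)
            other._accum(g)

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            if b.ndim >= 2:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
            else:  # (… n) @ (n,) -> outer product path
                ga = np.multiply.outer(g, b) if g.ndim else g * b
            if a.ndim >= 2:
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
            else:
                gb = np.multiply.outer(a, g) if g.ndim else a * g
            self._accum(ga)
            other._accum(gb)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._from_op(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._from_op(out_data, (self,), backward)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=np.float64)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, shape))

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Max along an axis; gradient flows to the (first) argmax only."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        out_data = np.squeeze(out_data, axis=axis)
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=np.float64)
            np.put_along_axis(
                full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
            )
            self._accum(full)

        return Tensor._from_op(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities ------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._from_op(np.where(mask, x.data, 0.0), (x,), lambda g: x._accum(g * mask))


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    factor = np.where(x.data > 0, 1.0, slope)
    return Tensor._from_op(x.data * factor, (x,), lambda g: x._accum(g * factor))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    return Tensor._from_op(s, (x,), lambda g: x._accum(g * s * (1.0 - s)))


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = x.data * s

    def backward(g):
        x._accum(g * (s + out * (1.0 - s)))

    return Tensor._from_op(out, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    return Tensor._from_op(t, (x,), lambda g: x._accum(g * (1.0 - t * t)))


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    return Tensor._from_op(e, (x,), lambda g: x._accum(g * e))


def log(x: Tensor) -> Tensor:
    return Tensor._from_op(np.log(x.data), (x,), lambda g: x._accum(g / x.data))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    return Tensor._from_op(y, (x,), backward)


# -- structural ops ------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._from_op(out_data, tensors, backward)


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Stack 1-D tensors into a matrix (rows)."""
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=0)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(g[i])

    return Tensor._from_op(out_data, tensors, backward)


def const_matmul(mat, x: Tensor) -> Tensor:
    """`mat @ x` where `mat` is a constant dense or scipy-sparse operator."""
    out_data = mat @ x.data

    def backward(g):
        if sp.issparse(mat):
            x._accum(mat.T @ g)
        else:
            x._accum(mat.T @ g)

    return Tensor._from_op(np.asarray(out_data), (x,), backward)


def segment_sum(x: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `x` into `num_segments` buckets given by `seg_ids`.

    Segments with no members yield zero rows.
    """
    out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, seg_ids, x.data)

    def backward(g):
        x._accum(g[seg_ids])

    return Tensor._from_op(out_data, (x,), backward)


def segment_softmax(x: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax over rows sharing a segment id, independently per column.

    Stabilised by subtracting the per-segment maximum (treated as a constant,
    which leaves the gradient unchanged because softmax is shift-invariant).
    """
    seg_max = np.full((num_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, seg_ids, x.data)
    z = x.data - seg_max[seg_ids]
    e = np.exp(np.clip(z, -700, 50))
    denom = np.zeros_like(seg_max)
    np.add.at(denom, seg_ids, e)
    y = e / denom[seg_ids]

    def backward(g):
        gy = g * y
        dot = np.zeros_like(seg_max)
        np.add.at(dot, seg_ids, gy)
        x._accum(gy - y * dot[seg_ids])

    return Tensor._from_op(y, (x,), backward)
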