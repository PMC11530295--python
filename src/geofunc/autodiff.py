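"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model in this package runs on plain NumPy; this module supplies the
gradient machinery for training and for gradient-based attribution.  It is a
deliberately small engine: dense float64 tensors, a static tape built as the
forward pass runs, and a topological-order backward sweep.  Only the
operations the geometric network actually uses are implemented (elementwise
arithmetic, broadcast-aware matmul, reductions, gather/segment-sum for
message passing, and a handful of nonlinearities).

Gradients accumulate on every tensor created with ``requires_grad=True`` and
on every tensor downstream of one, so intermediate activations (needed for
Grad-CAM) can be inspected after ``backward()``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        """Reverse sweep from this tensor; accumulates into `.grad` fields."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep for long chains)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray):
        # first accumulation borrows the buffer; later ones allocate a fresh
        # sum, so a buffer shared between consumers is never mutated
        if not t.requires_grad:
            return
        if t.grad is None:
            t.grad = g
        else:
            t.grad = t.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(self, _unbroadcast(g, self.data.shape))
            self._accum(other, _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(self, -g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(self, _unbroadcast(g * other.data, self.data.shape))
            self._accum(other, _unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def bwd(g):
            self._accum(self, _unbroadcast(g / other.data, self.data.shape))
            self._accum(other, _unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            self._accum(self, g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a2 = a[None, :]
                ga = np.matmul(g[..., None, :], np.swapaxes(b, -1, -2))[..., 0, :]
                gb = np.matmul(a2.T, g[..., None, :]) if b.ndim > 1 else np.outer(a, g)
                self._accum(self, _unbroadcast(ga, a.shape))
                self._accum(other, _unbroadcast(gb, b.shape))
                return
            if b.ndim == 1:
                ga = np.matmul(g[..., :, None], b[None, :])
                gb = np.matmul(np.swapaxes(a, -1, -2), g[..., :, None])[..., 0]
                self._accum(self, _unbroadcast(ga, a.shape))
                self._accum(other, _unbroadcast(gb, b.shape))
                return
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(self, _unbroadcast(ga, a.shape))
            self._accum(other, _unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), bwd)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            self._accum(self, g.reshape(old))

        return self._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g):
            self._accum(self, g.transpose(inv))

        return self._make(out_data, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(self, full)

        return self._make(out_data, (self,), bwd)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(self, np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(self, np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ---------------------------------------------------------- nonlinearity
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(self, g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            self._accum(self, g / self.data)

        return self._make(out_data, (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(self, g * 0.5 / out_data)

        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g):
            self._accum(self, g * mask)

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(self, g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(self, g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bwd)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes where x > lo."""
        mask = self.data > lo
        out_data = np.maximum(self.data, lo)

        def bwd(g):
            self._accum(self, g * mask)

        return self._make(out_data, (self,), bwd)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis` (max-shift is constant)."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(self, out_data * (g - dot))

        return self._make(out_data, (self,), bwd)

    def norm(self, axis: int = -1, keepdims: bool = False, eps: float = 1e-12):
        """L2 norm along `axis`; exact forward, eps-guarded backward at 0."""
        sq = (self.data**2).sum(axis=axis, keepdims=True)
        out_keep = np.sqrt(sq)
        out_data = out_keep if keepdims else np.squeeze(out_keep, axis=axis)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(self, g * self.data / np.maximum(out_keep, eps))

        return self._make(out_data, (self,), bwd)

    # --------------------------------------------------------- graph gather
    def gather(self, index: np.ndarray):
        """Rows `self[index]` along axis 0 (backward: scatter-add)."""
        index = np.asarray(index, dtype=np.int64)
        out_data = self.data[index]

        def bwd(g):
            self._accum(self, _scatter_add(g, index, self.data.shape[0]))

        return self._make(out_data, (self,), bwd)

    def segment_sum(self, index: np.ndarray, num_segments: int):
        """Sum rows into `num_segments` bins given per-row bin ids (axis 0)."""
        index = np.asarray(index, dtype=np.int64)
        out_data = _scatter_add(self.data, index, num_segments)

        def bwd(g):
            self._accum(self, g[index])

        return self._make(out_data, (self,), bwd)


def _scatter_add(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    """Sum `values` rows into `n` bins (sort + reduceat; faster than ufunc.at)."""
    out = np.zeros((n,) + values.shape[1:], dtype=np.float64)
    if len(index) == 0:
        return out
    order = np.argsort(index, kind="stable")
    sorted_idx = index[order]
    sorted_vals = values[order]
    boundaries = np.nonzero(np.diff(sorted_idx, prepend=-1))[0]
    sums = np.add.reduceat(sorted_vals, boundaries, axis=0)
    out[sorted_idx[boundaries]] = sums
    return out


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                Tensor._accum(t, piece)

        out._parents = tuple(tensors)
        out._backward = bwd
    return out


def stack(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:

        def bwd(g):
            for i, t in enumerate(tensors):
                Tensor._accum(t, np.take(g, i, axis=axis))

        out._parents = tuple(tensors)
        out._backward = bwd
    return out
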