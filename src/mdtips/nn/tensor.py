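"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates gradients
into every upstream tensor created with ``requires_grad=True``.  The op set is
deliberately small — elementwise arithmetic, (batched) matmul, reductions,
indexing/gather, scatter/segment sums and a few nonlinearities — which is
everything the encoders in this package need.  All computation is plain
NumPy, so results are deterministic on a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "take_axis1"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ----- construction helpers -------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # ----- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g, a=self, p=p):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if b.data.ndim == 1 and a.data.ndim == 1:
                a._accum(g * b.data)
                b._accum(g * a.data)
                return
            if b.data.ndim == 1:
                a._accum(np.expand_dims(g, -1) * b.data)
                b._accum(_unbroadcast(
                    (a.data * np.expand_dims(g, -1)).reshape(-1, b.data.shape[0]).sum(0),
                    b.data.shape))
                return
            if a.data.ndim == 1:
                a._accum(g @ np.swapaxes(b.data, -1, -2))
                b._accum(np.outer(a.data, g))
                return
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # ----- nonlinearities --------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            a._accum(g * o)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._accum(g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g, a=self, o=out_data):
            a._accum(g * o * (1.0 - o))

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, o=out_data):
            a._accum(g * (1.0 - o ** 2))

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            a._accum(g * m)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def leaky_relu(self, alpha: float = 0.01):
        pos = self.data > 0
        scale = np.where(pos, 1.0, alpha)

        def backward(g, a=self, s=scale):
            a._accum(g * s)

        return Tensor._from_op(self.data * scale, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g, a=self, s=sign):
            a._accum(g * s)

        return Tensor._from_op(np.abs(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # ----- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def backward(g, a=self, old=old_shape):
            a._accum(g.reshape(old))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, a1: int, a2: int):
        def backward(g, a=self, a1=a1, a2=a2):
            a._accum(np.swapaxes(g, a1, a2))

        return Tensor._from_op(np.swapaxes(self.data, a1, a2), (self,), backward)

    def transpose(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        """Supports basic slicing and 1-D integer-array gather (axis 0)."""
        if isinstance(idx, (list, np.ndarray)):
            idx = np.asarray(idx)
        out_data = self.data[idx]

        def backward(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._from_op(out_data, (self,), backward)

    # ----- autodiff driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free graph references so parameters keep only their grads
        for node in topo:
            if node is not self:
                node._backward = None
                node._parents = ()


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, parts=tuple(tensors), splits=splits, axis=axis):
        for part, piece in zip(parts, np.split(g, splits, axis=axis)):
            part._accum(piece)

    return Tensor._from_op(out_data, tensors, backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given by ``segment_ids``."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, x.data)

    def backward(g, a=x, ids=segment_ids):
        a._accum(g[ids])

    return Tensor._from_op(out_data, (x,), backward)


def take_axis1(x: Tensor, indices: np.ndarray) -> Tensor:
    """Gather columns ``indices`` (1-D, may repeat) from a 2-D tensor."""
    indices = np.asarray(indices, dtype=np.intp)
    out_data = x.data[:, indices]

    def backward(g, a=x, idx=indices):
        full = np.zeros_like(a.data)
        np.add.at(full.T, idx, g.T)  # scatter along axis 1
        a._accum(full)

    return Tensor._from_op(out_data, (x,), backward)
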