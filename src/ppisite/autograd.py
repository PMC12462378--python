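"""Compact reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the residue-graph network and the structured
loss need: broadcasting arithmetic, matrix products, pointwise nonlinearities,
reductions, row gather/scatter and segment sums (for edge-list message
passing), and concatenation.  All arithmetic is float64.

Gradients are accumulated by a topological-order sweep from the output node;
``Tensor.backward()`` may only be called on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "gather_rows",
    "scatter_rows",
    "segment_sum",
    "softmax",
    "clamp_min",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _scatter_add_rows(n_rows: int, idx: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Row scatter-add with duplicate indices (sort + reduceat; much faster
    than np.add.at for the edge-list sizes used here)."""
    out = np.zeros((n_rows,) + values.shape[1:])
    if idx.size == 0:
        return out
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(sorted_idx)) + 1])
    out[sorted_idx[starts]] = np.add.reduceat(values[order], starts, axis=0)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad):
            return (
                _unbroadcast(grad, self.data.shape),
                _unbroadcast(grad, other.data.shape),
            )

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.data.shape),
                _unbroadcast(grad * self.data, other.data.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad):
            return (
                _unbroadcast(grad / other.data, self.data.shape),
                _unbroadcast(-grad * self.data / other.data**2, other.data.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(grad):
            return (grad * e * self.data ** (e - 1),)

        return Tensor._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad):
            return (grad @ other.data.T, self.data.T @ grad)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        return Tensor._make(self.data.T, (self,), lambda g: (g.T,))

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    # ---- pointwise nonlinearities ---------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * factor, (self,), lambda g: (g * factor,))

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        orig_shape = self.data.shape

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, orig_shape).copy(),)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ---- indexing --------------------------------------------------------
    def __getitem__(self, key) -> "Tensor":
        orig_shape = self.data.shape
        is_row_index = isinstance(key, np.ndarray) and key.ndim == 1 and key.dtype.kind in "iu"

        def backward(grad):
            if is_row_index:
                return (_scatter_add_rows(orig_shape[0], key, grad),)
            out = np.zeros(orig_shape)
            np.add.at(out, key, grad)
            return (out,)

        return Tensor._make(self.data[key], (self,), backward)

    # ---- backward pass ---------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            grad = grads.pop(id(node), None)
            if grad is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = grad if node.grad is None else node.grad + grad
            if node._backward is None:
                continue
            parent_grads = node._backward(grad)
            for parent, pgrad in zip(node._parents, parent_grads):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pgrad
                else:
                    grads[id(parent)] = pgrad


# ---- free functions ------------------------------------------------------


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        return tuple(np.split(grad, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Rows ``t[idx]``; backward scatter-adds into the source rows."""
    return t[np.asarray(idx)]


def scatter_rows(t: Tensor, idx: np.ndarray, n_rows: int) -> Tensor:
    """Place rows of ``t`` at positions ``idx`` of an [n_rows x d] zero matrix."""
    idx = np.asarray(idx)
    out_data = np.zeros((n_rows,) + t.data.shape[1:])
    out_data[idx] = t.data
    return Tensor._make(out_data, (t,), lambda g: (g[idx],))


def segment_sum(t: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``n_segments`` buckets given per-row bucket ids."""
    segment_ids = np.asarray(segment_ids)
    out_data = _scatter_add_rows(n_segments, segment_ids, t.data)
    return Tensor._make(out_data, (t,), lambda g: (g[segment_ids],))


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(t.data.max(axis=axis, keepdims=True))  # constant: no grad
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def clamp_min(t: Tensor, floor: float) -> Tensor:
    """max(t, floor), differentiable where t > floor."""
    return (t - floor).relu() + floor
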