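"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine covering exactly the operations the
message-passing networks in this package need.  Every vector-Jacobian
product is itself expressed in terms of :class:`Tensor` operations, so the
graph built by a backward pass is differentiable again — second-order
derivatives (gradients of a loss that contains ``-dE/dx``) work out of the
box.

Leaf tensors are created in the module's compute dtype — float64 by
default, float32 inside training loops via :class:`compute_dtype`.  The
engine is not a general deep-learning framework: no views share memory, no
in-place ops, no GPU.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "grad",
    "concat",
    "gather",
    "scatter_add",
    "segment_sum",
    "softplus",
    "sigmoid",
    "silu",
    "compute_dtype",
    "get_compute_dtype",
]

# Dtype for newly created leaf/constant tensors.  Training loops switch to
# float32 for speed; evaluation and all oracle checks run in float64.
_DTYPE = np.float64


class compute_dtype:
    """Context manager setting the tensor-creation dtype (e.g. float32)."""

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype).type

    def __enter__(self):
        global _DTYPE
        self._saved = _DTYPE
        _DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global _DTYPE
        _DTYPE = self._saved
        return False


def get_compute_dtype():
    return _DTYPE


class Tensor:
    """A node in the computation graph wrapping a float ndarray."""

    __slots__ = ("data", "parents", "vjps", "requires_grad")

    def __init__(
        self,
        data,
        parents: tuple = (),
        vjps: tuple = (),
        requires_grad: bool = False,
    ):
        if parents:
            # op outputs keep whatever dtype numpy produced
            self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=_DTYPE)
        self.parents = parents
        self.vjps = vjps
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes=None):
        return transpose(self, axes)

    @property
    def T(self):
        return transpose(self, None)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# broadcasting helper: reduce g to `shape` by summing broadcast axes
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(g, b.shape),
        ),
    )


def sub(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data - b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(neg(g), b.shape),
        ),
    )


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(mul(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, a), b.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data / b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(div(g, b), a.shape),
            lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = astensor(a)
    return Tensor(-a.data, parents=(a,), vjps=(lambda g: neg(g),))


def power(a, exponent: float) -> Tensor:
    a = astensor(a)
    e = float(exponent)
    return Tensor(
        a.data**e,
        parents=(a,),
        vjps=(lambda g: mul(g, mul(e, power(a, e - 1.0))),),
    )


def matmul(a, b) -> Tensor:
    """Matrix product; supports (..., n, k) @ (k, m) and 2-D @ 2-D."""
    a, b = astensor(a), astensor(b)

    def vjp_a(g):
        return matmul(g, transpose(b, None)) if b.ndim == 2 else None

    def vjp_b(g):
        if a.ndim == 2:
            return matmul(transpose(a, None), g)
        k, m = b.shape
        a2 = reshape(a, (-1, k))
        g2 = reshape(g, (-1, m))
        return matmul(transpose(a2, None), g2)

    return Tensor(a.data @ b.data, parents=(a, b), vjps=(vjp_a, vjp_b))


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out = np.sum(a.data, axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            kept = (1,) * a.ndim
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            ax = tuple(i % a.ndim for i in ax)
            if keepdims:
                kept = g.shape
            else:
                kept = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
        return broadcast_to(reshape(g, kept), a.shape)

    return Tensor(out, parents=(a,), vjps=(vjp,))


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.size
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[i % a.ndim] for i in ax]))
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


def broadcast_to(a, shape) -> Tensor:
    a = astensor(a)
    shape = tuple(shape)
    return Tensor(
        np.broadcast_to(a.data, shape).copy(),
        parents=(a,),
        vjps=(lambda g: _unbroadcast(g, a.shape),),
    )


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return Tensor(
        a.data.reshape(shape),
        parents=(a,),
        vjps=(lambda g: reshape(g, a.shape),),
    )


def transpose(a, axes=None) -> Tensor:
    a = astensor(a)
    if axes is None:
        inv = None
    else:
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
    return Tensor(
        np.transpose(a.data, axes),
        parents=(a,),
        vjps=(lambda g: transpose(g, inv),),
    )


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)
    out = Tensor(out_data, parents=(a,), vjps=())
    out.vjps = (lambda g: mul(g, out),)
    return out


def log(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.log(a.data), parents=(a,), vjps=(lambda g: div(g, a),))


def sqrt(a) -> Tensor:
    a = astensor(a)
    out_data = np.sqrt(a.data)
    out = Tensor(out_data, parents=(a,), vjps=())
    out.vjps = (lambda g: div(mul(0.5, g), out),)
    return out


def tanh(a) -> Tensor:
    a = astensor(a)
    out_data = np.tanh(a.data)
    out = Tensor(out_data, parents=(a,), vjps=())
    out.vjps = (lambda g: mul(g, sub(1.0, mul(out, out))),)
    return out


def sin(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.sin(a.data), parents=(a,), vjps=(lambda g: mul(g, cos(a)),))


def cos(a) -> Tensor:
    a = astensor(a)
    return Tensor(
        np.cos(a.data), parents=(a,), vjps=(lambda g: neg(mul(g, sin(a))),)
    )


def sigmoid(a) -> Tensor:
    # stable and smooth; expressed via tanh so higher derivatives exist
    a = astensor(a)
    return mul(0.5, add(tanh(mul(0.5, a)), 1.0))


def softplus(a) -> Tensor:
    a = astensor(a)
    out = np.logaddexp(0.0, a.data)
    return Tensor(out, parents=(a,), vjps=(lambda g: mul(g, sigmoid(a)),))


def silu(a) -> Tensor:
    a = astensor(a)
    return mul(a, sigmoid(a))


def gather(a, index) -> Tensor:
    """Rows of ``a`` at integer ``index`` along axis 0."""
    a = astensor(a)
    index = np.asarray(index, dtype=np.intp)
    n = a.shape[0]
    return Tensor(
        a.data[index],
        parents=(a,),
        vjps=(lambda g: scatter_add(g, index, n),),
    )


def scatter_add(src, index, num_rows: int) -> Tensor:
    """out[index[k]] += src[k]; adjoint of :func:`gather`."""
    src = astensor(src)
    index = np.asarray(index, dtype=np.intp)
    out = np.zeros((num_rows,) + src.shape[1:], dtype=src.data.dtype)
    np.add.at(out, index, src.data)
    return Tensor(out, parents=(src,), vjps=(lambda g: gather(g, index),))


def segment_sum(a, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets."""
    return scatter_add(a, segment_ids, num_segments)


def concat(tensors: Sequence, axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    ax = axis % tensors[0].ndim
    sizes = [t.shape[ax] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def make_vjp(k):
        return lambda g: slice_axis(g, ax, int(offsets[k]), int(offsets[k + 1]))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=ax),
        parents=tuple(tensors),
        vjps=tuple(make_vjp(k) for k in range(len(tensors))),
    )


def slice_axis(a, axis: int, start: int, stop: int) -> Tensor:
    a = astensor(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, stop)
    n = a.shape[axis]
    return Tensor(
        a.data[tuple(idx)],
        parents=(a,),
        vjps=(lambda g: pad_axis(g, axis, start, n - stop),),
    )


def pad_axis(a, axis: int, before: int, after: int) -> Tensor:
    a = astensor(a)
    pads = [(0, 0)] * a.ndim
    pads[axis] = (before, after)
    n = a.shape[axis]
    return Tensor(
        np.pad(a.data, pads),
        parents=(a,),
        vjps=(lambda g: slice_axis(g, axis, before, before + n),),
    )


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _toposort(root: Tensor) -> list:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    grad_output: Tensor | None = None,
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned tensors stay connected to the
    graph, so they can be differentiated again.
    """
    if grad_output is None:
        if output.size != 1:
            raise ValueError("grad of a non-scalar output needs grad_output")
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): astensor(grad_output)}
    for node in reversed(_toposort(output)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in zip(node.parents, node.vjps):
            if not parent.requires_grad or vjp is None:
                continue
            pg = vjp(g)
            prev = grads.get(id(parent))
            grads[id(parent)] = pg if prev is None else add(prev, pg)
        # stash for inputs that are interior nodes
        if any(node is inp for inp in inputs):
            grads[id(node)] = g
    results = []
    for inp in inputs:
        g = grads.get(id(inp))
        if g is None:
            g = Tensor(np.zeros_like(inp.data))
        results.append(g if create_graph else g.detach())
    return results
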