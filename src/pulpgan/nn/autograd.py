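"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based engine in the style of HIPS/autograd: every primitive
records a vector-Jacobian product (VJP) that is itself expressed in terms of
primitives, so gradients of gradients are available (``create_graph=True``).
Higher-order support is required by the adversarial training loop, where the
gradient penalty differentiates the norm of an input gradient with respect to
the discriminator parameters.

Only the operations the package's networks and losses need are implemented.
All data is kept as float64 numpy arrays; the engine is deliberately small
and favours clarity over micro-optimisation (the networks it drives are
desk-scale).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the tape metadata needed for backpropagation."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")
    __array_priority__ = 100.0  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple[Tensor, ...] = ()
        self._vjp: Callable | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data, parents: Sequence["Tensor"], vjp: Callable) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims: bool = False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    @property
    def T(self):
        return transpose(self, None)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# -- broadcasting bookkeeping -------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Reduce a cotangent back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    # sum leading axes added by broadcasting
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# -- primitives ---------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor._result(a.data + b.data, (a, b), vjp)


def neg(a) -> Tensor:
    a = as_tensor(a)
    return Tensor._result(-a.data, (a,), lambda g: (neg(g),))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return Tensor._result(a.data * b.data, (a, b), vjp)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = _unbroadcast(div(g, b), a.shape)
        gb = _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)
        return ga, gb

    return Tensor._result(a.data / b.data, (a, b), vjp)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    exponent = float(exponent)

    def vjp(g):
        return (mul(g, mul(Tensor(exponent), power(a, exponent - 1.0))),)

    return Tensor._result(a.data**exponent, (a,), vjp)


def texp(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor._result(np.exp(a.data), (a,), None)
    out._vjp = lambda g: (mul(g, out),)
    return out


def tlog(a) -> Tensor:
    a = as_tensor(a)
    return Tensor._result(np.log(a.data), (a,), lambda g: (div(g, a),))


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor._result(np.tanh(a.data), (a,), None)
    out._vjp = lambda g: (mul(g, add(Tensor(1.0), neg(mul(out, out)))),)
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor._result(1.0 / (1.0 + np.exp(-a.data)), (a,), None)
    out._vjp = lambda g: (mul(g, mul(out, add(Tensor(1.0), neg(out)))),)
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = np.where(a.data > 0, 1.0, slope)

    def vjp(g):
        return (mul(g, Tensor(mask)),)

    return Tensor._result(a.data * mask, (a,), vjp)


def relu(a) -> Tensor:
    return leaky_relu(a, 0.0)


def tabs(a) -> Tensor:
    a = as_tensor(a)
    sign = np.sign(a.data)
    return Tensor._result(np.abs(a.data), (a,), lambda g: (mul(g, Tensor(sign)),))


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis,)
    else:
        axes = tuple(axis)
    kept_shape = tuple(
        1 if i in axes else s for i, s in enumerate(a.shape)
    )

    def vjp(g):
        return (broadcast_to(reshape(g, kept_shape), a.shape),)

    return Tensor._result(np.sum(a.data, axis=axes, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[i] for i in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)

    def vjp(g):
        return (_unbroadcast(g, a.shape),)

    return Tensor._result(np.broadcast_to(a.data, shape), (a,), vjp)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    orig = a.shape
    return Tensor._result(
        a.data.reshape(shape), (a,), lambda g: (reshape(g, orig),)
    )


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    axes = tuple(axes)
    inverse = tuple(np.argsort(axes))
    return Tensor._result(
        a.data.transpose(axes), (a,), lambda g: (transpose(g, inverse),)
    )


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def vjp(g):
        return matmul(g, transpose(b)), matmul(transpose(a), g)

    return Tensor._result(a.data @ b.data, (a, b), vjp)


def _swap_last(t: Tensor) -> Tensor:
    axes = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return transpose(t, axes)


def bmm(a, b) -> Tensor:
    """Batched matmul with numpy broadcasting of leading axes.

    Either operand may be 2-D (shared across the batch); its cotangent is
    then summed over the batch axes.
    """
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = bmm(g, _swap_last(b))
        gb = bmm(_swap_last(a), g)
        if ga.ndim > a.ndim:
            ga = tsum(ga, axis=tuple(range(ga.ndim - a.ndim)))
        if gb.ndim > b.ndim:
            gb = tsum(gb, axis=tuple(range(gb.ndim - b.ndim)))
        return ga, gb

    return Tensor._result(np.matmul(a.data, b.data), (a, b), vjp)


def take_columns(a, idx: np.ndarray) -> Tensor:
    """Gather columns of a 2-D tensor: (B, M) x idx(K,) -> (B, K).

    The adjoint is :func:`scatter_columns`; the pair being mutually adjoint
    linear maps is what makes second-order differentiation through the
    convolution layers exact.
    """
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    m = a.shape[1]
    return Tensor._result(
        a.data[:, idx], (a,), lambda g: (scatter_columns(g, idx, m),)
    )


_SCATTER_CACHE: dict = {}


def scatter_columns(v, idx: np.ndarray, width: int) -> Tensor:
    """Scatter-add columns: (B, K) x idx(K,) -> (B, width)."""
    v = as_tensor(v)
    idx = np.asarray(idx, dtype=np.intp)
    nb = v.shape[0]
    # bincount over flattened (batch, column) index pairs: much faster than
    # np.add.at for the repeated-index scatter pattern of col2im. The flat
    # index is cached per (index array, batch, width) since convolution
    # layers reuse the same gather pattern every step.
    key = (id(idx), nb, width)
    cached = _SCATTER_CACHE.get(key)
    if cached is None or cached[0] is not idx:
        flat = (np.arange(nb, dtype=np.intp)[:, None] * width
                + idx[None, :]).ravel()
        if len(_SCATTER_CACHE) > 128:
            _SCATTER_CACHE.clear()
        _SCATTER_CACHE[key] = (idx, flat)
    else:
        flat = cached[1]
    out = np.bincount(flat, weights=v.data.ravel(),
                      minlength=nb * width).reshape(nb, width)
    return Tensor._result(out, (v,), lambda g: (take_columns(g, idx),))


def pad2d(a, pad: int) -> Tensor:
    """Zero-pad the last two axes of a 4-D tensor symmetrically."""
    a = as_tensor(a)
    if pad == 0:
        return a
    width = ((0, 0), (0, 0), (pad, pad), (pad, pad))
    return Tensor._result(
        np.pad(a.data, width), (a,), lambda g: (crop2d(g, pad),)
    )


def crop2d(a, pad: int) -> Tensor:
    a = as_tensor(a)
    if pad == 0:
        return a
    return Tensor._result(
        a.data[:, :, pad:-pad, pad:-pad], (a,), lambda g: (pad2d(g, pad),)
    )


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        return tuple(
            narrow(g, axis, int(offsets[i]), sizes[i]) for i in range(len(tensors))
        )

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp
    )


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    a = as_tensor(a)
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, start + length)
    total = a.shape[axis]

    def vjp(g):
        return (pad_axis(g, axis, start, total),)

    return Tensor._result(a.data[tuple(sl)], (a,), vjp)


def pad_axis(a, axis: int, start: int, total: int) -> Tensor:
    a = as_tensor(a)
    length = a.shape[axis]
    width = [(0, 0)] * a.ndim
    width[axis] = (start, total - start - length)

    def vjp(g):
        return (narrow(g, axis, start, length),)

    return Tensor._result(np.pad(a.data, width), (a,), vjp)


# -- backward pass ------------------------------------------------------------


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent in node._parents:
            if parent.requires_grad and id(parent) not in seen:
                stack.append((parent, False))
    return order


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    grad_output: Tensor | None = None,
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own tape, so
    they can be differentiated again (needed for gradient penalties).
    """
    if not output.requires_grad:
        raise ValueError("output does not require grad; nothing to differentiate")
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        cotangents: dict[int, Tensor] = {id(output): grad_output}
        for node in reversed(_toposort(output)):
            g = cotangents.get(id(node))
            if g is None or node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in cotangents:
                    cotangents[id(parent)] = add(cotangents[id(parent)], pg)
                else:
                    cotangents[id(parent)] = pg
        result = []
        for t in inputs:
            g = cotangents.get(id(t))
            if g is None:
                g = Tensor(np.zeros_like(t.data))
            result.append(g)
    return result
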