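"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model components here (graph convolutions, small CNNs, fully connected
heads) are tiny by deep-learning standards, but the training strategy needs
*second-order* gradients: the outer meta-update differentiates the query loss
through a gradient step taken on the support loss. To make that exact rather
than approximated, :func:`grad` builds its vector-Jacobian products out of the
same differentiable operations, so the returned gradients are themselves graph
nodes that can be differentiated again (the ``create_graph`` idiom).

Only the operations the package needs are implemented: broadcasting
arithmetic, matmul, ReLU, reductions, max, reshaping/concatenation/slicing,
and an im2col/col2im pair for convolutions. ReLU and max use detached
subgradient masks, the standard convention for piecewise-linear ops.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "pow_",
    "sqrt",
    "matmul",
    "relu",
    "sum_",
    "mean",
    "max_",
    "reshape",
    "transpose",
    "concat",
    "getitem",
    "im2col",
    "col2im",
    "grad",
]


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "parents", "vjps", "requires_grad")

    def __init__(self, data, parents=(), vjps=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self.vjps = tuple(vjps)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # operator sugar -------------------------------------------------------
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

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def constant(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def parameter(x) -> Tensor:
    """A trainable leaf."""
    return Tensor(np.array(x, dtype=np.float64, copy=True), requires_grad=True)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# arithmetic


def add(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(g, b.shape),
        ),
    )


def sub(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    return Tensor(
        a.data - b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(neg(g), b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = constant(a)
    return Tensor(-a.data, parents=(a,), vjps=(lambda g: neg(g),))


def mul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(mul(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, a), b.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    return Tensor(
        a.data / b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(div(g, b), a.shape),
            lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def pow_(a, p: float) -> Tensor:
    a = constant(a)
    p = float(p)
    return Tensor(
        a.data**p,
        parents=(a,),
        vjps=(lambda g: mul(g, mul(p, pow_(a, p - 1.0))),),
    )


def sqrt(a) -> Tensor:
    return pow_(a, 0.5)


def matmul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError(f"matmul expects 2-D operands, got {a.shape} @ {b.shape}")
    if a.shape[1] != b.shape[0]:
        raise ValueError(f"matmul shape mismatch: {a.shape} @ {b.shape}")
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        vjps=(
            lambda g: matmul(g, transpose(b)),
            lambda g: matmul(transpose(a), g),
        ),
    )


def relu(a) -> Tensor:
    a = constant(a)
    mask = Tensor((a.data > 0).astype(np.float64))
    return Tensor(
        np.maximum(a.data, 0.0),
        parents=(a,),
        vjps=(lambda g: mul(g, mask),),
    )


# ---------------------------------------------------------------------------
# reductions


def _norm_axes(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(ax % ndim for ax in axis)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = constant(a)
    axes = _norm_axes(axis, a.ndim)
    out = a.data.sum(axis=axes, keepdims=keepdims)

    def vjp(g):
        if not keepdims:
            shp = list(a.shape)
            for ax in axes:
                shp[ax] = 1
            g = reshape(g, tuple(shp))
        return mul(g, Tensor(np.ones(a.shape)))

    return Tensor(out, parents=(a,), vjps=(vjp,))


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = constant(a)
    axes = _norm_axes(axis, a.ndim)
    n = int(np.prod([a.shape[ax] for ax in axes])) if axes else 1
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def max_(a, axis: int, keepdims=False) -> Tensor:
    """Maximum along one axis; gradient splits equally among tied maxima."""
    a = constant(a)
    ax = axis % a.ndim
    out = a.data.max(axis=ax, keepdims=True)
    m = (a.data == out).astype(np.float64)
    m /= m.sum(axis=ax, keepdims=True)
    mask = Tensor(m)

    def vjp(g):
        if not keepdims:
            shp = list(a.shape)
            shp[ax] = 1
            g = reshape(g, tuple(shp))
        return mul(g, mask)

    return Tensor(
        out if keepdims else out.squeeze(axis=ax), parents=(a,), vjps=(vjp,)
    )


# ---------------------------------------------------------------------------
# shape ops


def reshape(a, shape) -> Tensor:
    a = constant(a)
    orig = a.shape
    return Tensor(
        a.data.reshape(shape),
        parents=(a,),
        vjps=(lambda g: reshape(g, orig),),
    )


def transpose(a, axes=None) -> Tensor:
    a = constant(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return Tensor(
        a.data.transpose(axes),
        parents=(a,),
        vjps=(lambda g: transpose(g, inv),),
    )


def concat(tensors, axis=0) -> Tensor:
    tensors = [constant(t) for t in tensors]
    ax = axis % tensors[0].ndim
    sizes = [t.shape[ax] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            idx = [slice(None)] * g.ndim
            idx[ax] = slice(int(offsets[i]), int(offsets[i + 1]))
            return getitem(g, tuple(idx))

        return vjp

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=ax),
        parents=tuple(tensors),
        vjps=tuple(make_vjp(i) for i in range(len(tensors))),
    )


def getitem(a, idx) -> Tensor:
    """Basic (slice/int) indexing; the adjoint scatters into zeros."""
    a = constant(a)
    shape = a.shape

    def vjp(g):
        return _scatter(g, shape, idx)

    return Tensor(a.data[idx], parents=(a,), vjps=(vjp,))


def _scatter(g: Tensor, shape, idx) -> Tensor:
    """Linear adjoint of basic indexing, itself differentiable."""

    def vjp(h):
        return getitem(h, idx)

    out = np.zeros(shape)
    out[idx] = g.data
    return Tensor(out, parents=(g,), vjps=(vjp,))


# ---------------------------------------------------------------------------
# convolution support


def _im2col_np(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    cols = np.empty((oh * ow, c * kh * kw))
    k = 0
    for ci in range(c):
        for i in range(kh):
            for j in range(kw):
                cols[:, k] = x[ci, i : i + oh, j : j + ow].ravel()
                k += 1
    return cols


def _col2im_np(cols: np.ndarray, shape, kh: int, kw: int) -> np.ndarray:
    c, h, w = shape
    oh, ow = h - kh + 1, w - kw + 1
    out = np.zeros(shape)
    k = 0
    for ci in range(c):
        for i in range(kh):
            for j in range(kw):
                out[ci, i : i + oh, j : j + ow] += cols[:, k].reshape(oh, ow)
                k += 1
    return out


def im2col(a, kh: int, kw: int) -> Tensor:
    """Unfold a (C, H, W) tensor into (H'·W', C·kh·kw) sliding patches."""
    a = constant(a)
    shape = a.shape
    return Tensor(
        _im2col_np(a.data, kh, kw),
        parents=(a,),
        vjps=(lambda g: col2im(g, shape, kh, kw),),
    )


def col2im(a, shape, kh: int, kw: int) -> Tensor:
    a = constant(a)
    return Tensor(
        _col2im_np(a.data, shape, kh, kw),
        parents=(a,),
        vjps=(lambda g: im2col(g, kh, kw),),
    )


# ---------------------------------------------------------------------------
# backward pass


def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # children before parents when reversed... already post-order


def grad(output: Tensor, wrt, create_graph: bool = False):
    """Gradients of a scalar ``output`` with respect to each tensor in ``wrt``.

    With ``create_graph=True`` the returned tensors remain connected to the
    graph and can be differentiated again (needed for the second-order
    meta-update). Tensors in ``wrt`` that the output does not depend on get a
    zero gradient of matching shape.
    """
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")
    wrt = list(wrt)
    wrt_ids = {id(t) for t in wrt}
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape))}
    for node in reversed(_toposort(output)):
        if id(node) in wrt_ids:
            g = grads.get(id(node))
        else:
            g = grads.pop(id(node), None)
        if g is None:
            continue
        for p, vjp in zip(node.parents, node.vjps):
            if not p.requires_grad:
                continue
            contrib = vjp(g)
            prev = grads.get(id(p))
            grads[id(p)] = contrib if prev is None else add(prev, contrib)
    out = []
    for w in wrt:
        g = grads.get(id(w))
        if g is None:
            g = Tensor(np.zeros(w.shape))
        out.append(g if create_graph else g.detach())
    return out
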