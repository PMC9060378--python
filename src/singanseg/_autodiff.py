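"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each operation records its parent
tensors and a vector-Jacobian-product closure. The VJP closures are
themselves written in terms of traced operations, so gradients are
ordinary graph nodes and can be differentiated again. Higher-order
derivatives (needed for the critic's gradient penalty) therefore work
without any special casing.

Only the primitives required by this package are provided; in particular
convolution is expressed as ``im2col`` + ``matmul`` so that the pair of
linear adjoints ``im2col``/``col2im`` are the only image-specific
primitives.

Dtype policy: results follow numpy promotion; python scalars are coerced
to the tensor's dtype so float32 graphs stay float32.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "grad",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "pow_const",
    "sqrt_",
    "tanh_",
    "leaky_relu",
    "relu",
    "clip_",
    "sum_",
    "mean_",
    "mse",
    "broadcast_to",
    "reshape",
    "transpose",
    "matmul",
    "pad2d",
    "crop2d",
    "im2col",
    "col2im",
    "avgpool2",
]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self) -> "no_grad":
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc) -> bool:
        _GRAD_ENABLED.pop()
        return False


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, np.ndarray):
            self.data = data
        else:
            self.data = np.asarray(data, dtype=float)
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp: Callable | None = None

    # -- conveniences ---------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other, like=self))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, as_tensor(other, like=self))

    def __rsub__(self, other):
        return sub(as_tensor(other, like=self), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other, like=self))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, as_tensor(other, like=self))

    def __rtruediv__(self, other):
        return div(as_tensor(other, like=self), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, c):
        return pow_const(self, c)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other, like=self))


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    """Wrap ``x`` as a constant Tensor, matching ``like``'s dtype for scalars."""
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


def _node(data: np.ndarray, parents: tuple, vjp: Callable) -> Tensor:
    t = Tensor(data)
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        t.requires_grad = True
        t._parents = parents
        t._vjp = vjp
    return t


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    gs = g.data.shape
    if gs == tuple(shape):
        return g
    extra = len(gs) - len(shape)
    axes = tuple(range(extra)) + tuple(
        i + extra for i, s in enumerate(shape) if s == 1 and gs[i + extra] != 1
    )
    if axes:
        g = sum_(g, axis=axes, keepdims=False)
    return reshape(g, shape)


# ---------------------------------------------------------------------------
# elementwise primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), vjp)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return (_unbroadcast(g, a.data.shape), _unbroadcast(neg(g), b.data.shape))

    return _node(a.data - b.data, (a, b), vjp)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return (_unbroadcast(mul(g, b), a.data.shape), _unbroadcast(mul(g, a), b.data.shape))

    return _node(a.data * b.data, (a, b), vjp)


def div(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        ga = _unbroadcast(div(g, b), a.data.shape)
        gb = _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.data.shape)
        return (ga, gb)

    return _node(a.data / b.data, (a, b), vjp)


def neg(a: Tensor) -> Tensor:
    def vjp(g):
        return (neg(g),)

    return _node(-a.data, (a,), vjp)


def pow_const(a: Tensor, c: float) -> Tensor:
    def vjp(g):
        return (mul(g, mul(as_tensor(c, like=a), pow_const(a, c - 1))),)

    return _node(a.data ** c, (a,), vjp)


def sqrt_(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def vjp(g):
        return (div(g, mul(as_tensor(2.0, like=out), out)),)

    out = _node(out_data, (a,), vjp)
    return out


def tanh_(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def vjp(g):
        one = as_tensor(1.0, like=out)
        return (mul(g, sub(one, mul(out, out))),)

    out = _node(out_data, (a,), vjp)
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = np.where(a.data >= 0, 1.0, slope).astype(a.data.dtype)

    def vjp(g):
        return (mul(g, Tensor(mask)),)

    return _node(np.where(a.data >= 0, a.data, a.data * slope), (a,), vjp)


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def clip_(a: Tensor, lo: float, hi: float) -> Tensor:
    mask = ((a.data >= lo) & (a.data <= hi)).astype(a.data.dtype)

    def vjp(g):
        return (mul(g, Tensor(mask)),)

    return _node(np.clip(a.data, lo, hi), (a,), vjp)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    in_shape = a.data.shape
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        gg = g
        if not keepdims:
            if axis is None:
                gg = reshape(gg, (1,) * len(in_shape))
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ks = list(in_shape)
                for i in ax:
                    ks[i % len(in_shape)] = 1
                gg = reshape(gg, tuple(ks))
        return (broadcast_to(gg, in_shape),)

    return _node(data, (a,), vjp)


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for i in ax:
            n *= a.data.shape[i]
    return mul(sum_(a, axis=axis, keepdims=keepdims), as_tensor(1.0 / n, like=a))


def mse(a: Tensor, b: Tensor) -> Tensor:
    d = sub(a, b)
    return mean_(mul(d, d))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    in_shape = a.data.shape

    def vjp(g):
        return (_unbroadcast(g, in_shape),)

    return _node(np.broadcast_to(a.data, shape), (a,), vjp)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    in_shape = a.data.shape

    def vjp(g):
        return (reshape(g, in_shape),)

    return _node(np.reshape(a.data, shape), (a,), vjp)


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = tuple(int(i) for i in np.argsort(axes))

    def vjp(g):
        return (transpose(g, inv),)

    return _node(a.data.transpose(axes), (a,), vjp)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product."""

    def vjp(g):
        return (matmul(g, transpose(b, (1, 0))), matmul(transpose(a, (1, 0)), g))

    return _node(a.data @ b.data, (a, b), vjp)


# ---------------------------------------------------------------------------
# spatial primitives (arrays laid out channels-first: C x H x W)
# ---------------------------------------------------------------------------

def _pads4(p) -> tuple:
    if isinstance(p, int):
        return (p, p, p, p)
    return tuple(p)


def pad2d(a: Tensor, p) -> Tensor:
    """Zero-pad the last two axes by (top, bottom, left, right)."""
    t, b, l, r = _pads4(p)
    width = [(0, 0)] * (a.data.ndim - 2) + [(t, b), (l, r)]

    def vjp(g):
        return (crop2d(g, (t, b, l, r)),)

    return _node(np.pad(a.data, width), (a,), vjp)


def crop2d(a: Tensor, p) -> Tensor:
    """Remove (top, bottom, left, right) rows/cols from the last two axes."""
    t, b, l, r = _pads4(p)
    sl = (Ellipsis, slice(t, a.data.shape[-2] - b), slice(l, a.data.shape[-1] - r))

    def vjp(g):
        return (pad2d(g, (t, b, l, r)),)

    return _node(a.data[sl], (a,), vjp)


def _im2col_np(x: np.ndarray, k: int) -> np.ndarray:
    C, H, W = x.shape
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # (C, OH, OW, k, k) -> (C, k, k, OH, OW) -> (C*k*k, OH*OW)
    return v.transpose(0, 3, 4, 1, 2).reshape(C * k * k, -1)


def _col2im_np(cols: np.ndarray, chw: tuple, k: int) -> np.ndarray:
    C, H, W = chw
    OH, OW = H - k + 1, W - k + 1
    cols = cols.reshape(C, k, k, OH, OW)
    out = np.zeros((C, H, W), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, i : i + OH, j : j + OW] += cols[:, i, j]
    return out


def im2col(a: Tensor, k: int) -> Tensor:
    """Unfold kxk patches of a CxHxW tensor into a (C*k*k) x (OH*OW) matrix."""
    chw = a.data.shape

    def vjp(g):
        return (col2im(g, chw, k),)

    return _node(_im2col_np(a.data, k), (a,), vjp)


def col2im(a: Tensor, chw: tuple, k: int) -> Tensor:
    """Adjoint of :func:`im2col` (overlap-add fold)."""

    def vjp(g):
        return (im2col(g, k),)

    return _node(_col2im_np(a.data, chw, k), (a,), vjp)


def avgpool2(a: Tensor) -> Tensor:
    """2x2 average pooling on the last two axes (odd edges are cropped)."""
    C, H, W = a.data.shape
    if H % 2 or W % 2:
        a = crop2d(a, (0, H % 2, 0, W % 2))
        C, H, W = a.data.shape
    x = reshape(a, (C, H // 2, 2, W // 2, 2))
    return mul(sum_(x, axis=(2, 4)), as_tensor(0.25, like=a))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def grad(output: Tensor, inputs: Sequence[Tensor], grad_output: Tensor | None = None) -> list:
    """Gradients of ``output`` w.r.t. ``inputs``.

    The returned gradients are themselves Tensors connected to the graph,
    so they can be differentiated again (double backprop).
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))

    # iterative post-order DFS over the requires_grad subgraph
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        t, done = stack.pop()
        if done:
            topo.append(t)
            continue
        if id(t) in visited or not t.requires_grad:
            continue
        visited.add(id(t))
        stack.append((t, True))
        for p in t._parents:
            stack.append((p, False))

    grads: dict[int, Tensor] = {id(output): grad_output}
    for t in reversed(topo):
        g = grads.get(id(t))
        if g is None or t._vjp is None:
            continue
        for p, pg in zip(t._parents, t._vjp(g)):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg

    out = []
    for i in inputs:
        gi = grads.get(id(i))
        out.append(gi if gi is not None else Tensor(np.zeros_like(i.data)))
    return out
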