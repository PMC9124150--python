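"""Compact reverse-mode automatic differentiation on numpy arrays.

The engine is a tape of :class:`Tensor` nodes; each op builds a child node
holding closures that map the child's upstream gradient to contributions for
each parent.  ``Tensor.backward()`` topologically sorts the graph and
accumulates gradients.  Only the ops the segmentation networks need are
implemented: elementwise arithmetic, reductions, activations, N-D
convolution (stride/dilation), max pooling, nearest and linear upsampling,
concatenation and global average pooling.  Feature tensors carry no batch
axis — layout is ``(channels, *spatial)`` with 2D or 3D spatial parts;
minibatches are formed by accumulating gradients across cases.

Convolutions are evaluated as a sum over kernel offsets of 1x1 products
(one BLAS ``tensordot`` per kernel tap), which keeps memory flat and is fast
at the 32--128 voxel grid sizes this package targets.
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[tuple["Tensor", Callable[[Array], Array]]] = ()):
        self.data = np.asarray(data)
        self.grad: Array | None = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in self._parents)

    # -- graph -----------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            g = node.grad
            for parent, fn in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = fn(g)
                parent.grad = contrib if parent.grad is None else parent.grad + contrib

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, power(as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def sum(self, axis=None, keepdims: bool = False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _coerce_scalars(a, b):
    """Python-number operands adopt the other tensor's float dtype so
    float32 graphs are not silently promoted to float64."""
    if isinstance(a, Tensor) and isinstance(b, (int, float)) \
            and np.issubdtype(a.data.dtype, np.floating):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(b, Tensor) and isinstance(a, (int, float)) \
            and np.issubdtype(b.data.dtype, np.floating):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    return a, b


# -- elementwise -----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _coerce_scalars(a, b)
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return Tensor(out, parents=[
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(g, b.data.shape)),
    ])


def mul(a, b) -> Tensor:
    a, b = _coerce_scalars(a, b)
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return Tensor(out, parents=[
        (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
        (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
    ])


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** exponent
    return Tensor(out, parents=[
        (a, lambda g: g * exponent * a.data ** (exponent - 1.0)),
    ])


def log(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(np.log(a.data), parents=[(a, lambda g: g / a.data)])


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return Tensor(out, parents=[(a, lambda g: g * out)])


def clip(a, lo: float, hi: float) -> Tensor:
    """Value clamp; gradient is zero where the clamp is active."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)
    return Tensor(out, parents=[(a, lambda g: g * inside)])


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    out = np.empty_like(a.data, dtype=a.data.dtype)
    pos = a.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    out[~pos] = ex / (1.0 + ex)
    return Tensor(out, parents=[(a, lambda g: g * out * (1.0 - out))])


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, parents=[(a, lambda g: g * mask)])


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    factor = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype, copy=False)
    return Tensor(a.data * factor, parents=[(a, lambda g: g * factor)])


def softmax(a, axis: int = 0) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return out * (g - dot)

    return Tensor(out, parents=[(a, back)])


# -- reductions ------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        g = np.asarray(g)
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return np.broadcast_to(g, a.data.shape).copy()

    return Tensor(out, parents=[(a, back)])


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return Tensor(a.data.reshape(shape),
                  parents=[(a, lambda g: g.reshape(a.data.shape))])


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def make_back(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, parents=[(t, make_back(i)) for i, t in enumerate(tensors)])


def global_avg_pool(a, keepdims: bool = False) -> Tensor:
    """Mean of each channel over all spatial positions. Input ``(C, *spatial)``."""
    a = as_tensor(a)
    axes = tuple(range(1, a.data.ndim))
    return tmean(a, axis=axes, keepdims=keepdims)


# -- convolution -----------------------------------------------------------

def _same_pad(kernel: tuple[int, ...], dilation: int) -> list[tuple[int, int]]:
    pads = []
    for k in kernel:
        total = dilation * (k - 1)
        pads.append((total // 2, total - total // 2))
    return pads


def conv(x, weight, bias=None, stride: int = 1, dilation: int = 1,
         padding: str = "same") -> Tensor:
    """N-D convolution (cross-correlation).

    ``x``: ``(C_in, *spatial)``; ``weight``: ``(C_out, C_in, *kernel)``;
    ``bias``: ``(C_out,)`` or None.  ``padding`` is ``"same"`` (stride must
    be 1) or ``"valid"``.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    nd = x.data.ndim - 1
    kernel = weight.data.shape[2:]
    if len(kernel) != nd:
        raise ValueError(f"kernel rank {len(kernel)} does not match spatial rank {nd}")
    if x.data.shape[0] != weight.data.shape[1]:
        raise ValueError(
            f"input has {x.data.shape[0]} channels but kernel expects {weight.data.shape[1]}")
    if padding == "same":
        if stride != 1:
            raise ValueError("'same' padding requires stride 1")
        pads = _same_pad(kernel, dilation)
    elif padding == "valid":
        pads = [(0, 0)] * nd
    else:
        raise ValueError(f"unknown padding {padding!r}")

    if stride == 1:
        return _conv_flat(x, weight, bias, dilation, pads)
    return _conv_im2col(x, weight, bias, stride, dilation, pads)


def _conv_flat(x: Tensor, weight: Tensor, bias, dilation: int,
               pads: list[tuple[int, int]]) -> Tensor:
    """Stride-1 convolution as GEMMs on flat offset views (zero-copy).

    With zero padding, a kernel tap is a constant offset in the flattened
    padded array; accumulating one (C_out, C_in) x (C_in, Q) product per tap
    over a shared flat window and cropping the valid block yields the
    same-padded convolution without materialising an im2col matrix.
    """
    nd = x.data.ndim - 1
    kernel = weight.data.shape[2:]
    cin, cout = x.data.shape[0], weight.data.shape[0]
    dtype = np.result_type(x.data, weight.data)
    xpad = np.pad(x.data, [(0, 0)] + pads) if any(p != (0, 0) for p in pads) else x.data
    psp = xpad.shape[1:]
    out_sp = tuple(psp[i] - dilation * (kernel[i] - 1) for i in range(nd))
    row_strides = [int(np.prod(psp[i + 1:])) for i in range(nd)]
    taps = list(np.ndindex(*kernel))
    offsets = [dilation * sum(t[i] * row_strides[i] for i in range(nd)) for t in taps]
    n_tot = int(np.prod(psp))
    q = n_tot - max(offsets)
    xflat = xpad.reshape(cin, n_tot)

    acc = np.zeros((cout, q), dtype=dtype)
    for tap, off in zip(taps, offsets):
        w_tap = np.ascontiguousarray(weight.data[(slice(None), slice(None)) + tap],
                                     dtype=dtype)
        acc += w_tap @ xflat[:, off:off + q]
    valid = (slice(None),) + tuple(slice(0, s) for s in out_sp)
    full = np.zeros((cout, n_tot), dtype=dtype)
    full[:, :q] = acc
    out = full.reshape((cout,) + psp)[valid].copy()
    if bias is not None:
        bias = as_tensor(bias)
        out += bias.data.reshape((cout,) + (1,) * nd)

    sp_axes = tuple(range(1, nd + 1))

    def back_x(g):
        gacc = np.zeros((cout,) + psp, dtype=dtype)
        gacc[valid] = g
        gacc = gacc.reshape(cout, n_tot)[:, :q]
        gx = np.zeros((cin, n_tot), dtype=dtype)
        for tap, off in zip(taps, offsets):
            w_tap = np.ascontiguousarray(
                weight.data[(slice(None), slice(None)) + tap], dtype=dtype)
            gx[:, off:off + q] += w_tap.T @ gacc
        gxpad = gx.reshape((cin,) + psp)
        if xpad is x.data:
            return gxpad
        unpad = (slice(None),) + tuple(
            slice(pads[i][0], psp[i] - pads[i][1]) for i in range(nd))
        return gxpad[unpad]

    def back_w(g):
        gacc = np.zeros((cout,) + psp, dtype=dtype)
        gacc[valid] = g
        gacc = gacc.reshape(cout, n_tot)[:, :q]
        gw = np.empty_like(weight.data)
        for tap, off in zip(taps, offsets):
            gw[(slice(None), slice(None)) + tap] = gacc @ xflat[:, off:off + q].T
        return gw

    parents = [(x, back_x), (weight, back_w)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=sp_axes)))
    return Tensor(out, parents=parents)


def _conv_im2col(x: Tensor, weight: Tensor, bias, stride: int, dilation: int,
                 pads: list[tuple[int, int]]) -> Tensor:
    """Strided convolution via an explicit im2col matrix and one GEMM."""
    nd = x.data.ndim - 1
    kernel = weight.data.shape[2:]
    cin, cout = x.data.shape[0], weight.data.shape[0]
    n_tap = int(np.prod(kernel))
    dtype = np.result_type(x.data, weight.data)
    xpad = np.pad(x.data, [(0, 0)] + pads) if any(p != (0, 0) for p in pads) else x.data
    sp = xpad.shape[1:]
    out_sp = tuple((sp[i] - dilation * (kernel[i] - 1) - 1) // stride + 1 for i in range(nd))
    n_vox = int(np.prod(out_sp))

    taps = list(np.ndindex(*kernel))
    slices_per_tap = []
    cols = np.empty((cin, n_tap) + out_sp, dtype=dtype)
    for ki, tap in enumerate(taps):
        sl = (slice(None),) + tuple(
            slice(dilation * tap[i], dilation * tap[i] + stride * (out_sp[i] - 1) + 1,
                  stride) for i in range(nd))
        slices_per_tap.append(sl)
        cols[:, ki] = xpad[sl]
    cols = cols.reshape(cin * n_tap, n_vox)
    w2d = np.ascontiguousarray(weight.data.reshape(cout, cin * n_tap), dtype=dtype)
    out = (w2d @ cols).reshape((cout,) + out_sp)
    if bias is not None:
        bias = as_tensor(bias)
        out += bias.data.reshape((cout,) + (1,) * nd)

    sp_axes = tuple(range(1, nd + 1))

    def back_x(g):
        g2d = g.reshape(cout, n_vox)
        gcols = (w2d.T @ g2d).reshape((cin, n_tap) + out_sp)
        gxpad = np.zeros_like(xpad, dtype=gcols.dtype)
        for ki, sl in enumerate(slices_per_tap):
            gxpad[sl] += gcols[:, ki]
        if xpad is x.data:
            return gxpad
        unpad = (slice(None),) + tuple(
            slice(pads[i][0], gxpad.shape[1 + i] - pads[i][1]) for i in range(nd))
        return gxpad[unpad]

    def back_w(g):
        g2d = g.reshape(cout, n_vox)
        return (g2d @ cols.T).reshape(weight.data.shape)

    parents = [(x, back_x), (weight, back_w)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=sp_axes)))
    return Tensor(out, parents=parents)


# -- pooling / resampling --------------------------------------------------

def max_pool(x, size: int = 2) -> Tensor:
    """Non-overlapping max pooling with window = stride = ``size``."""
    x = as_tensor(x)
    nd = x.data.ndim - 1
    sp = x.data.shape[1:]
    if any(s % size for s in sp):
        raise ValueError(f"spatial shape {sp} not divisible by pool size {size}")
    shape = (x.data.shape[0],) + tuple(
        itertools.chain.from_iterable((s // size, size) for s in sp))
    axes = tuple(2 * i + 2 for i in range(nd))
    xm = x.data.reshape(shape)
    out = xm.max(axis=axes)

    def back(g):
        out_e = np.expand_dims(out, axes)
        mask = xm == out_e
        cnt = mask.sum(axis=axes, keepdims=True)
        gm = mask * (np.expand_dims(g, axes) / cnt)
        return gm.reshape(x.data.shape)

    return Tensor(out, parents=[(x, back)])


def upsample_nearest(x, factor: int = 2) -> Tensor:
    x = as_tensor(x)
    nd = x.data.ndim - 1
    out = x.data
    for ax in range(1, nd + 1):
        out = np.repeat(out, factor, axis=ax)

    def back(g):
        for ax in range(1, nd + 1):
            n = g.shape[ax] // factor
            g = g.reshape(g.shape[:ax] + (n, factor) + g.shape[ax + 1:]).sum(axis=ax + 1)
        return g

    return Tensor(out, parents=[(x, back)])


def _linear_interp_matrix(src: int, dst: int) -> Array:
    """Dense (dst, src) linear-interpolation matrix, align-corners convention."""
    a = np.zeros((dst, src))
    if src == 1:
        a[:, 0] = 1.0
        return a
    if dst == 1:
        a[0, 0] = 1.0
        return a
    pos = np.linspace(0.0, src - 1.0, dst)
    lo = np.floor(pos).astype(int)
    lo = np.minimum(lo, src - 2)
    w = pos - lo
    rows = np.arange(dst)
    a[rows, lo] += 1.0 - w
    a[rows, lo + 1] += w
    return a


def upsample_linear(x, target_spatial: tuple[int, ...]) -> Tensor:
    """Bi/tri-linear resize of ``(C, *spatial)`` to ``target_spatial`` (>= input)."""
    x = as_tensor(x)
    nd = x.data.ndim - 1
    if len(target_spatial) != nd:
        raise ValueError("target rank mismatch")
    for s, t in zip(x.data.shape[1:], target_spatial):
        if t < s:
            raise ValueError(f"upsample target {target_spatial} smaller than input "
                             f"{x.data.shape[1:]} on some axis")
    dtype = x.data.dtype if np.issubdtype(x.data.dtype, np.floating) else np.float64
    mats = [_linear_interp_matrix(x.data.shape[1 + i], target_spatial[i]).astype(dtype)
            for i in range(nd)]

    def apply(data: Array, matrices: list[Array]) -> Array:
        for i, m in enumerate(matrices):
            ax = 1 + i
            data = np.moveaxis(np.tensordot(m, data, axes=([1], [ax])), 0, ax)
        return data

    out = apply(x.data, mats)
    return Tensor(out, parents=[(x, lambda g: apply(g, [m.T for m in mats]))])
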