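"""Minimal reverse-mode automatic differentiation for dense 3-D arrays.

The registration objective is differentiated end to end: through the
convolutional sub-networks, the scaling-and-squaring integrator, trilinear
warping, the Gaussian smoothing layer and the similarity/regularity terms.
This module supplies exactly the operator set that chain needs, on NumPy
arrays in float32, with gradients accumulated by a topological-order sweep.

Conventions
-----------
* Feature maps and vector fields are ``(C, D, H, W)``; scalar volumes may be
  any shape (elementwise ops and reductions are shape-agnostic).
* ``Tensor`` wraps an ``np.ndarray``; ``requires_grad`` marks graph leaves
  (parameters). Constants never allocate gradient buffers.
* All convolutions use kernel size 3 unless stated otherwise; padding is
  explicit per op (zero padding inside the networks, replicate padding for
  the smoothing / pooling primitives, matching standard practice).
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv3d",
    "conv_transpose3d",
    "conv1d_axis",
    "forward_diff",
    "grid_sample",
    "leaky_relu",
    "relu",
    "sqrt",
    "square",
]

_DTYPE = np.float32


class Tensor:
    """A node in the computation graph: value, gradient and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        """Accumulate gradients of ``self`` (a scalar) into graph leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda a, b, g: g, lambda a, b, g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda a, b, g: g, lambda a, b, g: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda a, b, g: g * b, lambda a, b, g: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda a, b, g: g / b,
                       lambda a, b, g: -g * a / (b * b))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return _unary(self, np.negative, lambda x, g: -g)

    # -- reductions --------------------------------------------------------

    def sum(self) -> "Tensor":
        out_data = self.data.sum(dtype=_DTYPE)
        shape = self.data.shape

        def bw(g):
            self._accum(np.broadcast_to(g, shape))

        return _make(out_data, (self,), bw)

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)

    def abs(self) -> "Tensor":
        return _unary(self, np.abs, lambda x, g: g * np.sign(x))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    need = any(p.requires_grad for p in parents)
    if not need:
        return Tensor(data)
    out = Tensor(data, requires_grad=True, parents=parents, backward=backward)
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    if g.shape == tuple(shape):
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = g.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a, b, fn, da, db) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = fn(a.data, b.data)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(da(a.data, b.data, g), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(db(a.data, b.data, g), b.data.shape))

    return _make(data, (a, b), bw)


def _unary(x, fn, dx) -> Tensor:
    x = as_tensor(x)
    data = fn(x.data)

    def bw(g):
        x._accum(dx(x.data, g))

    return _make(data, (x,), bw)


# ---------------------------------------------------------------------------
# Elementwise nonlinearities
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    data = np.where(mask, x.data, slope * x.data)

    def bw(g):
        x._accum(np.where(mask, g, slope * g))

    return _make(data, (x,), bw)


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    data = np.sqrt(x.data)

    def bw(g):
        x._accum(g * 0.5 / np.maximum(data, 1e-12))

    return _make(data, (x,), bw)


def square(x: Tensor) -> Tensor:
    return x * x


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return _make(data, tuple(tensors), bw)


# ---------------------------------------------------------------------------
# 3-D convolution (zero padding) and its transpose
# ---------------------------------------------------------------------------

def _out_size(d: int, k: int, stride: int, pad: int) -> int:
    return (d + 2 * pad - k) // stride + 1


def _conv3d_fwd(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    # accumulate one GEMM per kernel offset; avoids materializing im2col windows
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    do, ho, wo = (_out_size(d, k, stride, pad) for d in x.shape[1:])
    y = np.zeros((w.shape[0], do, ho, wo), dtype=_DTYPE)
    for i, j, l in itertools.product(range(k), repeat=3):
        xs = xp[:,
                i:i + stride * (do - 1) + 1:stride,
                j:j + stride * (ho - 1) + 1:stride,
                l:l + stride * (wo - 1) + 1:stride]
        y += np.tensordot(w[:, :, i, j, l], xs, axes=(1, 0))
    return y


def _conv3d_input_grad(gy: np.ndarray, w: np.ndarray, stride: int, pad: int,
                       spatial) -> np.ndarray:
    """Adjoint of `_conv3d_fwd` with respect to its input."""
    k = w.shape[-1]
    c_in = w.shape[1]
    D, H, W = spatial
    do, ho, wo = gy.shape[1:]
    gxp = np.zeros((c_in, D + 2 * pad, H + 2 * pad, W + 2 * pad), dtype=_DTYPE)
    for i, j, l in itertools.product(range(k), repeat=3):
        contrib = np.tensordot(w[:, :, i, j, l], gy, axes=(0, 0))
        gxp[:,
            i:i + stride * do:stride,
            j:j + stride * ho:stride,
            l:l + stride * wo:stride] += contrib
    if pad:
        gxp = gxp[:, pad:-pad, pad:-pad, pad:-pad]
    return gxp


def _conv3d_weight_grad(x: np.ndarray, gy: np.ndarray, stride: int, pad: int,
                        k: int) -> np.ndarray:
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    do, ho, wo = gy.shape[1:]
    gw = np.empty((gy.shape[0], x.shape[0], k, k, k), dtype=_DTYPE)
    for i, j, l in itertools.product(range(k), repeat=3):
        xs = xp[:,
                i:i + stride * (do - 1) + 1:stride,
                j:j + stride * (ho - 1) + 1:stride,
                l:l + stride * (wo - 1) + 1:stride]
        gw[:, :, i, j, l] = np.tensordot(gy, xs, axes=([1, 2, 3], [1, 2, 3]))
    return gw


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 1) -> Tensor:
    """3-D convolution; ``x`` is (C_in, D, H, W), ``w`` is (C_out, C_in, k, k, k)."""
    x, w = as_tensor(x), as_tensor(w)
    data = _conv3d_fwd(x.data, w.data, stride, pad)
    if b is not None:
        b = as_tensor(b)
        data = data + b.data[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)
    k = w.data.shape[-1]

    def bw(g):
        if x.requires_grad:
            x._accum(_conv3d_input_grad(g, w.data, stride, pad, x.data.shape[1:]))
        if w.requires_grad:
            w._accum(_conv3d_weight_grad(x.data, g, stride, pad, k))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))

    return _make(data, parents, bw)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, pad: int = 1,
                     out_spatial=None) -> Tensor:
    """Transposed 3-D convolution, the exact adjoint of ``conv3d``.

    ``x`` is (C_in, d, h, w); ``w`` is (C_in, C_out, k, k, k) — i.e. the weight
    of the conv this op is the transpose of. Output spatial size defaults to
    ``stride * input`` per axis (kernel 3, stride 2, output sized to double).
    """
    x, w = as_tensor(x), as_tensor(w)
    if out_spatial is None:
        out_spatial = tuple(stride * s for s in x.data.shape[1:])
    data = _conv3d_input_grad(x.data, w.data, stride, pad, out_spatial)
    if b is not None:
        b = as_tensor(b)
        data = data + b.data[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)
    k = w.data.shape[-1]

    def bw(g):
        if x.requires_grad:
            x._accum(_conv3d_fwd(g, w.data, stride, pad))
        if w.requires_grad:
            w._accum(_conv3d_weight_grad(g, x.data, stride, pad, k))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))

    return _make(data, parents, bw)


# ---------------------------------------------------------------------------
# Separable 1-D convolution with replicate padding (smoothing, box filters)
# ---------------------------------------------------------------------------

def conv1d_axis(x: Tensor, kernel: np.ndarray, axis: int) -> Tensor:
    """Convolve along one spatial axis with replicate-border padding.

    ``kernel`` is a fixed (non-trainable) odd-length 1-D filter. Output shape
    equals input shape. The adjoint folds pad-region gradients back onto the
    border samples, making the op exactly self-consistent under replicate
    padding.
    """
    x = as_tensor(x)
    kernel = np.asarray(kernel, dtype=_DTYPE)
    K = kernel.size
    p = K // 2
    xm = np.moveaxis(x.data, axis, -1)
    D = xm.shape[-1]
    xp = np.pad(xm, [(0, 0)] * (xm.ndim - 1) + [(p, p)], mode="edge")
    win = sliding_window_view(xp, K, axis=-1)
    ym = np.einsum("...dk,k->...d", win, kernel, optimize=True).astype(_DTYPE)
    data = np.moveaxis(ym, -1, axis)

    def bw(g):
        gm = np.moveaxis(g, axis, -1)
        gxp = np.zeros_like(xp)
        for t in range(K):
            gxp[..., t:t + D] += kernel[t] * gm
        gx = gxp[..., p:p + D].copy()
        if p:
            gx[..., 0] += gxp[..., :p].sum(axis=-1)
            gx[..., -1] += gxp[..., p + D:].sum(axis=-1)
        x._accum(np.moveaxis(gx, -1, axis))

    return _make(data, (x,), bw)


def forward_diff(x: Tensor, axis: int) -> Tensor:
    """Forward difference along ``axis``; last slice zero (replicate boundary)."""
    x = as_tensor(x)
    data = np.zeros_like(x.data)
    lead = [slice(None)] * x.data.ndim
    hi, lo = lead.copy(), lead.copy()
    hi[axis] = slice(1, None)
    lo[axis] = slice(None, -1)
    hi, lo = tuple(hi), tuple(lo)
    body = lead.copy()
    body[axis] = slice(None, -1)
    body = tuple(body)
    data[body] = x.data[hi] - x.data[lo]

    def bw(g):
        gx = np.zeros_like(g)
        gx[hi] += g[body]
        gx[lo] -= g[body]
        x._accum(gx)

    return _make(data, (x,), bw)


# ---------------------------------------------------------------------------
# Trilinear sampling with border clamping
# ---------------------------------------------------------------------------

def grid_sample(x: Tensor, coords: Tensor) -> Tensor:
    """Sample ``x`` (C, D, H, W) at absolute voxel positions ``coords`` (3, ...).

    Trilinear interpolation; positions outside the grid are clamped to the
    border. Differentiable in both the image and the sampling positions
    (position gradients vanish where clamping is active).
    """
    from . import _kernels

    x, coords = as_tensor(x), as_tensor(coords)
    C = x.data.shape[0]
    out_spatial = coords.data.shape[1:]
    n = int(np.prod(out_spatial))
    cflat = np.ascontiguousarray(coords.data.reshape(3, n))
    img = np.ascontiguousarray(x.data)
    data = _kernels.trilinear_forward(img, cflat).reshape((C,) + tuple(out_spatial))

    def bw(g):
        gflat = np.ascontiguousarray(g.reshape(C, n))
        gimg, gcoords = _kernels.trilinear_backward(
            img, cflat, gflat, x.requires_grad, coords.requires_grad)
        if x.requires_grad:
            x._accum(gimg)
        if coords.requires_grad:
            coords._accum(gcoords.reshape((3,) + tuple(out_spatial)))

    return _make(data, (x, coords), bw)
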