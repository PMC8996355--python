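"""Geometric primitives for diffeomorphic registration.

Containers for volumes, velocity fields, displacement fields and label maps,
plus the transform chain they flow through: average-pooling pyramids,
stationary-velocity-field (SVF) integration by scaling and squaring, trilinear
warping and composition, Gaussian smoothing and Jacobian-determinant analysis.

Conventions (fixed across the package):

* Coordinates are 0-based voxel indices. A displacement field ``u`` encodes
  the map ``x -> x + u(x)``.
* Velocity and displacement vectors are stored in full-resolution voxel
  units at every pyramid level, so multi-level accumulation is plain
  addition; sampling on a coarser grid divides by the grid scale factor.
* Out-of-bounds samples are clamped to the border.

The ``*_t`` functions operate on autodiff tensors (channel-first arrays) and
carry gradients; the top-level functions wrap them for the NumPy-backed
containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Volume",
    "VelocityField",
    "DisplacementField",
    "LabelMap",
    "build_pyramid",
    "avg_pool3",
    "integrate_svf",
    "compose_displacements",
    "warp_volume",
    "upsample_field",
    "gaussian_smooth_field",
    "jacobian_determinant",
    "identity_grid",
    "integrate_svf_t",
    "compose_t",
    "warp_t",
    "upsample_t",
    "gaussian_smooth_t",
    "gaussian_kernel1d",
    "DEFAULT_STEPS",
    "DEFAULT_SIGMA",
    "DEFAULT_KSIZE",
]

DEFAULT_STEPS = 7        # scaling-and-squaring time steps
DEFAULT_SIGMA = 1.732    # smoothing-layer Gaussian sigma, voxels
DEFAULT_KSIZE = 3        # smoothing-layer kernel size per axis


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3-D scalar image with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got {self.data.ndim}-D")
        if not np.isfinite(self.data).all():
            raise ValueError("Volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class VelocityField:
    """A stationary velocity field: (3, D, H, W), full-resolution voxel units."""

    data: np.ndarray
    level: int = 1

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(
                f"VelocityField must have shape (3, D, H, W), got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("VelocityField contains non-finite values")

    @property
    def grid_shape(self):
        return self.data.shape[1:]


@dataclass
class DisplacementField:
    """A displacement field u with map x -> x + u(x): (3, D, H, W), voxel units."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(
                f"DisplacementField must have shape (3, D, H, W), got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("DisplacementField contains non-finite values")

    @property
    def grid_shape(self):
        return self.data.shape[1:]


@dataclass
class LabelMap:
    """Integer anatomical labels; 0 is background."""

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"LabelMap must be 3-D, got {arr.ndim}-D")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("LabelMap values must be integers")
            arr = rounded.astype(np.int32)
        if (arr < 0).any():
            raise ValueError("LabelMap values must be non-negative")
        self.data = arr.astype(np.int32)

    @property
    def shape(self):
        return self.data.shape

    def labels(self, include_background: bool = False) -> np.ndarray:
        vals = np.unique(self.data)
        return vals if include_background else vals[vals != 0]


# ---------------------------------------------------------------------------
# Identity grids (cached)
# ---------------------------------------------------------------------------

_GRID_CACHE: dict[tuple, np.ndarray] = {}


def identity_grid(shape) -> np.ndarray:
    """Return the (3, D, H, W) array of voxel coordinates for ``shape``."""
    key = tuple(int(s) for s in shape)
    grid = _GRID_CACHE.get(key)
    if grid is None:
        axes = [np.arange(s, dtype=np.float32) for s in key]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)
        _GRID_CACHE[key] = grid
    return grid


# ---------------------------------------------------------------------------
# Pyramid
# ---------------------------------------------------------------------------

def avg_pool3(data: np.ndarray) -> np.ndarray:
    """Average pooling, 3x3x3 kernel, stride 2, replicate padding of 1 voxel.

    Each output dimension is exactly half the (even) input dimension.
    """
    if any(s % 2 for s in data.shape):
        raise ValueError(f"avg_pool3 needs even dimensions, got {data.shape}")
    xp = np.pad(data, 1, mode="edge")
    win = sliding_window_view(xp, (3, 3, 3))
    win = win[::2, ::2, ::2]
    return win.mean(axis=(-3, -2, -1), dtype=np.float64).astype(np.float32)


def build_pyramid(vol: Volume, levels: int) -> list[Volume]:
    """Multi-resolution pyramid by recursive average pooling.

    Returns ``levels`` volumes ordered coarse to fine; the last element is the
    original volume. Every dimension of ``vol`` must be divisible by
    ``2**(levels - 1)``.
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    div = 2 ** (levels - 1)
    if any(s % div for s in vol.shape):
        raise ValueError(
            f"shape {vol.shape} not divisible by 2^{levels - 1}; pad first")
    out = [vol]
    cur = vol
    for i in range(1, levels):
        factor = 2 ** i
        spacing = tuple(s * 2 for s in cur.spacing)
        cur = Volume(avg_pool3(cur.data), spacing=spacing)
        out.append(cur)
    return out[::-1]


# ---------------------------------------------------------------------------
# Warping, composition, SVF integration (tensor level)
# ---------------------------------------------------------------------------

def warp_t(img: Tensor, disp: Tensor) -> Tensor:
    """Trilinear warp of channel-first image ``img`` by displacement ``disp``."""
    grid = identity_grid(disp.shape[1:])
    coords = disp + Tensor(grid)
    return ad.grid_sample(img, coords)


def compose_t(outer: Tensor, inner: Tensor) -> Tensor:
    """r(x) = inner(x) + outer(x + inner(x)) — composition of displacements."""
    grid = identity_grid(inner.shape[1:])
    coords = inner + Tensor(grid)
    return inner + ad.grid_sample(outer, coords)


def integrate_svf_t(v: Tensor, steps: int = DEFAULT_STEPS) -> Tensor:
    """Integrate an SVF to a displacement by scaling and squaring.

    The field is scaled by 2^-steps and self-composed ``steps`` times,
    approximating the time-1 flow of dD/dt = v(D).
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    u = v * float(2.0 ** -steps)
    for _ in range(steps):
        u = compose_t(u, u)
    return u


def upsample_t(f: Tensor, target_shape) -> Tensor:
    """Channel-wise trilinear interpolation onto ``target_shape``.

    Grid corners map to grid corners, so nodes of an axis-aligned refinement
    reproduce source values exactly. Vector values are not rescaled (they are
    stored in full-resolution voxel units at every level).
    """
    src = f.shape[1:]
    target_shape = tuple(int(s) for s in target_shape)
    if any(t < s for t, s in zip(target_shape, src)):
        raise ValueError(f"cannot shrink {src} to {target_shape}")
    if tuple(src) == target_shape:
        return f
    axes = []
    for s, t in zip(src, target_shape):
        scale = (s - 1) / (t - 1) if t > 1 else 0.0
        axes.append(np.arange(t, dtype=np.float32) * scale)
    coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)
    return ad.grid_sample(f, Tensor(coords))


def gaussian_kernel1d(sigma: float, ksize: int) -> np.ndarray:
    """Truncated, renormalized 1-D Gaussian kernel."""
    if ksize % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {ksize}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    r = np.arange(ksize, dtype=np.float64) - ksize // 2
    k = np.exp(-0.5 * (r / sigma) ** 2)
    return (k / k.sum()).astype(np.float32)


def gaussian_smooth_t(u: Tensor, sigma: float = DEFAULT_SIGMA,
                      ksize: int = DEFAULT_KSIZE) -> Tensor:
    """Separable Gaussian smoothing per channel, replicate borders."""
    k = gaussian_kernel1d(sigma, ksize)
    for axis in (1, 2, 3):
        u = ad.conv1d_axis(u, k, axis)
    return u


# ---------------------------------------------------------------------------
# Container-level wrappers
# ---------------------------------------------------------------------------

def integrate_svf(v: VelocityField, steps: int = DEFAULT_STEPS) -> DisplacementField:
    return DisplacementField(integrate_svf_t(Tensor(v.data), steps).data)


def compose_displacements(outer: DisplacementField,
                          inner: DisplacementField) -> DisplacementField:
    if outer.grid_shape != inner.grid_shape:
        raise ValueError(
            f"grid mismatch: {outer.grid_shape} vs {inner.grid_shape}")
    return DisplacementField(compose_t(Tensor(outer.data), Tensor(inner.data)).data)


def warp_volume(vol, u: DisplacementField, mode: str = "trilinear"):
    """Resample a Volume (trilinear) or LabelMap (nearest) through ``x + u(x)``."""
    if u.grid_shape != tuple(vol.shape):
        raise ValueError(f"field grid {u.grid_shape} != volume shape {vol.shape}")
    if mode == "trilinear":
        data = np.asarray(vol.data, dtype=np.float32)
        out = warp_t(Tensor(data[None]), Tensor(u.data)).data[0]
        if isinstance(vol, Volume):
            return Volume(out, spacing=vol.spacing)
        return Volume(out)
    if mode == "nearest":
        coords = identity_grid(u.grid_shape) + u.data
        idx = []
        for a, s in enumerate(u.grid_shape):
            idx.append(np.clip(np.rint(coords[a]), 0, s - 1).astype(np.intp))
        out = vol.data[tuple(idx)]
        if isinstance(vol, LabelMap):
            return LabelMap(out)
        return Volume(out, spacing=getattr(vol, "spacing", (1.0, 1.0, 1.0)))
    raise ValueError(f"unknown interpolation mode: {mode!r}")


def upsample_field(f, target_shape):
    """Upsample a velocity or displacement field; returns the same kind."""
    out = upsample_t(Tensor(f.data), target_shape).data
    if isinstance(f, VelocityField):
        return VelocityField(out, level=f.level)
    return DisplacementField(out)


def gaussian_smooth_field(u, sigma: float = DEFAULT_SIGMA,
                          ksize: int = DEFAULT_KSIZE):
    out = gaussian_smooth_t(Tensor(u.data), sigma, ksize).data
    if isinstance(u, VelocityField):
        return VelocityField(out, level=u.level)
    return DisplacementField(out)


def jacobian_determinant(u: DisplacementField) -> Volume:
    """Per-voxel determinant of the deformation gradient d(x + u(x))/dx.

    Central differences in the interior, one-sided on the faces; the identity
    map yields 1 everywhere.
    """
    if any(s < 3 for s in u.grid_shape):
        raise ValueError(f"grid must be >= 3 per axis, got {u.grid_shape}")
    d = np.asarray(u.data, dtype=np.float64)
    # J[a][b] = d(x_a + u_a)/dx_b
    J = [[None] * 3 for _ in range(3)]
    for a in range(3):
        grads = np.gradient(d[a], axis=(0, 1, 2))
        for b in range(3):
            g = grads[b]
            if a == b:
                g = g + 1.0
            J[a][b] = g
    det = (J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
           - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
           + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0]))
    return Volume(det.astype(np.float32))
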