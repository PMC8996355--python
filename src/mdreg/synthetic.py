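"""Synthetic phantoms and ground-truth diffeomorphic warps.

Stands in for skull-stripped, affinely aligned T1 volumes: smooth,
piecewise-homogeneous phantoms of nested labeled ellipsoidal shells, with
per-seed random axes and orientation for inter-subject variability, deformed
by known random smooth velocity fields whose integrated warp is verified
fold-free at generation. Everything is bitwise reproducible under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import core
from .core import Volume, LabelMap, VelocityField, integrate_svf, \
    jacobian_determinant, warp_volume

__all__ = ["PhantomSpec", "WarpSpec", "make_phantom", "make_random_svf",
           "make_pair", "recovery_benchmark_pair", "small_benchmark_pair"]


@dataclass
class PhantomSpec:
    shape: tuple = (48, 48, 48)
    n_shells: int = 3
    intensity_levels: tuple | None = None   # background + one per shell
    noise_sd: float = 0.02
    blur_sigma: float = 1.0
    texture_amp: float = 0.3    # smooth multiplicative intensity texture
    texture_sigma: float = 2.0  # correlation length of the texture, voxels
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError(f"shape must be 3 axes each >= 16, got {self.shape}")
        if self.n_shells < 1:
            raise ValueError("need at least one shell")
        if self.intensity_levels is None:
            # background 0, then distinct levels; non-monotone like real tissue
            base = np.linspace(1.0, 0.35, self.n_shells)
            base[1::2] += 0.25
            self.intensity_levels = (0.0, *np.round(base, 3))
        if len(self.intensity_levels) != self.n_shells + 1:
            raise ValueError("need n_shells + 1 intensity levels")
        if len(set(self.intensity_levels)) != len(self.intensity_levels):
            raise ValueError("intensity levels must be distinct")


@dataclass
class WarpSpec:
    smoothness_sigma: float = 4.0   # voxels
    amplitude: float = 3.0          # max |v|, voxels
    magnitude_gamma: float = 0.5    # <1 pushes typical magnitudes toward the max
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.smoothness_sigma <= 0:
            raise ValueError("smoothness_sigma must be positive")
        if not 0 < self.magnitude_gamma <= 1:
            raise ValueError("magnitude_gamma must be in (0, 1]")


def ellipsoid_geometry(spec: PhantomSpec):
    """Deterministic per-seed shell geometry: center, rotation, semi-axes.

    Returns ``(center, rotation, semi_axes)`` where ``semi_axes[k]`` holds the
    three semi-axis lengths of shell ``k`` (outermost first); shells are
    concentric and share the orientation, so they nest by construction.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.shape, dtype=np.float64)
    center = shape / 2.0 + rng.uniform(-0.03, 0.03, 3) * shape
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    outer = 0.40 * shape * rng.uniform(0.85, 1.0, 3)
    fracs = np.linspace(1.0, 0.35, spec.n_shells)
    semi = np.stack([outer * f for f in fracs])
    return center, q, semi


def _shell_labels(spec: PhantomSpec) -> np.ndarray:
    center, rot, semi = ellipsoid_geometry(spec)
    grid = core.identity_grid(spec.shape).astype(np.float64)
    rel = grid.reshape(3, -1) - center[:, None]
    local = rot.T @ rel
    labels = np.zeros(rel.shape[1], dtype=np.int32)
    for k in range(spec.n_shells):
        q = ((local / semi[k][:, None]) ** 2).sum(axis=0)
        labels[q <= 1.0] = k + 1
    return labels.reshape(spec.shape)


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Blurred, noised multi-shell ellipsoid image with exact integer labels.

    A smooth multiplicative random texture (correlation length
    ``texture_sigma``) emulates the intensity variation of real tissue; it
    rides on the anatomy, so it deforms with it and gives local similarity
    measures signal away from tissue boundaries, as in real MR images.
    """
    labels = _shell_labels(spec)
    intens = np.asarray(spec.intensity_levels, dtype=np.float32)
    img = intens[labels].astype(np.float64)
    rng = np.random.default_rng(spec.seed + 1)
    if spec.texture_amp > 0:
        tex = gaussian_filter(rng.standard_normal(spec.shape), spec.texture_sigma)
        tex /= max(np.abs(tex).max(), 1e-12)
        img = img * (1.0 + spec.texture_amp * tex)
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        img = np.clip(img, 0.0, None)
    return Volume(img.astype(np.float32)), LabelMap(labels)


def make_random_svf(shape, spec: WarpSpec) -> VelocityField:
    """Random smooth velocity field with a fold-free integrated warp.

    Per-channel white noise is Gaussian-smoothed and rescaled so the largest
    vector magnitude equals ``amplitude``; the draw is repeated with a fresh
    sub-seed (at most 10 times) until the integrated displacement has a
    strictly positive Jacobian determinant everywhere.
    """
    if spec.amplitude == 0:
        return VelocityField(np.zeros((3,) + tuple(shape), np.float32))
    for attempt in range(10):
        rng = np.random.default_rng((spec.seed, attempt))
        noise = rng.standard_normal((3,) + tuple(shape))
        v = np.stack([gaussian_filter(c, spec.smoothness_sigma) for c in noise])
        mag = np.sqrt((v ** 2).sum(axis=0))
        peak = mag.max()
        if peak == 0:
            continue
        v /= peak
        mag /= peak
        if spec.magnitude_gamma < 1:
            # compress the magnitude distribution toward its peak so the
            # warp is substantial across the volume, not only at one spot
            v *= (mag + 1e-12) ** (spec.magnitude_gamma - 1.0)
        v = (v * spec.amplitude).astype(np.float32)
        fieldv = VelocityField(v)
        det = jacobian_determinant(integrate_svf(fieldv)).data
        if det.min() > 0:
            return fieldv
    raise ValueError(
        f"could not generate a fold-free warp with amplitude {spec.amplitude}; "
        "reduce amplitude or increase smoothness_sigma")


def recovery_benchmark_pair(seed: int):
    """The package's standard desk-scale recovery benchmark.

    A 48^3 five-shell phantom deformed by a fold-free warp of 4-voxel peak
    magnitude (smoothness 4 voxels): large relative to the shell thickness,
    so the initial label overlap is substantially degraded and recovery
    exercises the full coarse-to-fine path.
    """
    ph = PhantomSpec(shape=(48, 48, 48), n_shells=5, seed=seed)
    wp = WarpSpec(amplitude=4.0, smoothness_sigma=4.0, seed=seed)
    return make_pair(ph, wp)


def small_benchmark_pair(seed: int):
    """A lighter 32^3 benchmark pair for sweep-style experiments."""
    ph = PhantomSpec(shape=(32, 32, 32), n_shells=4, seed=seed)
    wp = WarpSpec(amplitude=3.0, smoothness_sigma=3.5, seed=seed)
    return make_pair(ph, wp)


def make_pair(phantom: PhantomSpec, warp: WarpSpec):
    """Fixed/moving phantom pair related by a known diffeomorphic warp.

    The moving image is the fixed phantom resampled through the integrated
    ground-truth velocity field (labels via nearest neighbor). Returns
    ``(fixed, moving, labels_f, labels_m, gt_svf)``.
    """
    fixed, labels_f = make_phantom(phantom)
    gt_svf = make_random_svf(phantom.shape, warp)
    disp = integrate_svf(gt_svf)
    moving = warp_volume(fixed, disp, mode="trilinear")
    labels_m = warp_volume(labels_f, disp, mode="nearest")
    return fixed, moving, labels_f, labels_m, gt_svf
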