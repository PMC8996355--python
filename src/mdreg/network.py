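"""Convolutional sub-networks regressing incremental velocity fields.

One dedicated sub-network per resolution level. All share the same encoder
layout — a 16-filter convolution followed by three 32-filter convolutions,
all stride 2, shrinking the full-resolution 2-channel input (moving/warped
moving concatenated with fixed) by 16. The decoder has 1, 2 or 3 transposed
convolutions of 32 filters (stride 2) for levels 1..3, so the predicted
velocity grids sit at 1/8, 1/4 and 1/2 of the input resolution. A head of
two convolutions (32 then 16 filters) and a 3-channel output convolution
completes each sub-network. Kernels are 3x3x3 throughout; activations are
LeakyReLU (slope 0.2) everywhere except the output, whose weights start at
zero so the untrained model is the identity transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import core
from .core import DEFAULT_STEPS, DEFAULT_SIGMA, DEFAULT_KSIZE

__all__ = ["Subnetwork", "MultiResState", "build_subnetwork",
           "forward_multires", "pad_to_divisible", "crop_field", "normalize_volume"]

ENCODER_CHANNELS = (16, 32, 32, 32)
DECODER_FILTERS = 32
HEAD_CHANNELS = (32, 16)
KERNEL = 3
LEAKY_SLOPE = 0.2


def _he_init(rng: np.random.Generator, c_out: int, c_in: int) -> np.ndarray:
    fan_in = c_in * KERNEL ** 3
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal((c_out, c_in, KERNEL, KERNEL, KERNEL)) * std
            ).astype(np.float32)


@dataclass
class Subnetwork:
    """Parameter container and forward pass for one resolution level."""

    level: int
    params: dict = field(default_factory=dict)

    @property
    def scale(self) -> int:
        """Downsampling factor of the output velocity grid (8, 4 or 2)."""
        return 2 ** (4 - self.level)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def forward(self, x: Tensor) -> Tensor:
        """Map a (2, D, H, W) input to a (3, D/scale, ...) velocity field."""
        p = self.params
        h = x
        for i in range(len(ENCODER_CHANNELS)):
            h = ad.conv3d(h, p[f"enc{i}_w"], p[f"enc{i}_b"], stride=2, pad=1)
            h = ad.leaky_relu(h, LEAKY_SLOPE)
        for i in range(self.level):
            h = ad.conv_transpose3d(h, p[f"dec{i}_w"], p[f"dec{i}_b"],
                                    stride=2, pad=1)
            h = ad.leaky_relu(h, LEAKY_SLOPE)
        for i in range(len(HEAD_CHANNELS)):
            h = ad.conv3d(h, p[f"head{i}_w"], p[f"head{i}_b"], stride=1, pad=1)
            h = ad.leaky_relu(h, LEAKY_SLOPE)
        return ad.conv3d(h, p["out_w"], p["out_b"], stride=1, pad=1)

    def state_arrays(self) -> dict:
        return {k: v.data for k, v in self.params.items()}

    def load_state_arrays(self, state: dict) -> None:
        for k, t in self.params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != t.data.shape:
                raise ValueError(f"parameter {k}: shape {arr.shape} != {t.data.shape}")
            t.data = arr


def build_subnetwork(level: int, rng: np.random.Generator | int | None = None
                     ) -> Subnetwork:
    """Construct the sub-network for ``level`` in {1, 2, 3}.

    He-initialized hidden layers; the output convolution is zero-initialized
    so the first forward pass emits a zero velocity field.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"level must be in 1..3, got {level}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p: dict[str, Tensor] = {}
    c_in = 2
    for i, c_out in enumerate(ENCODER_CHANNELS):
        p[f"enc{i}_w"] = Tensor(_he_init(rng, c_out, c_in), requires_grad=True)
        p[f"enc{i}_b"] = Tensor(np.zeros(c_out, np.float32), requires_grad=True)
        c_in = c_out
    for i in range(level):
        # transposed-conv weights are stored as (C_in, C_out, k, k, k)
        w = _he_init(rng, DECODER_FILTERS, c_in).transpose(1, 0, 2, 3, 4)
        p[f"dec{i}_w"] = Tensor(np.ascontiguousarray(w), requires_grad=True)
        p[f"dec{i}_b"] = Tensor(np.zeros(DECODER_FILTERS, np.float32),
                                requires_grad=True)
        c_in = DECODER_FILTERS
    for i, c_out in enumerate(HEAD_CHANNELS):
        p[f"head{i}_w"] = Tensor(_he_init(rng, c_out, c_in), requires_grad=True)
        p[f"head{i}_b"] = Tensor(np.zeros(c_out, np.float32), requires_grad=True)
        c_in = c_out
    p["out_w"] = Tensor(np.zeros((3, c_in, KERNEL, KERNEL, KERNEL), np.float32),
                        requires_grad=True)
    p["out_b"] = Tensor(np.zeros(3, np.float32), requires_grad=True)
    return Subnetwork(level=level, params=p)


# ---------------------------------------------------------------------------
# Shape plumbing
# ---------------------------------------------------------------------------

def pad_to_divisible(data: np.ndarray, div: int = 16):
    """Symmetrically zero-pad each axis up to the next multiple of ``div``.

    Returns the padded array and the per-axis crop slices that undo it.
    """
    pads, crops = [], []
    for s in data.shape:
        target = ((s + div - 1) // div) * div
        extra = target - s
        lo = extra // 2
        pads.append((lo, extra - lo))
        crops.append(slice(lo, lo + s))
    return np.pad(data, pads), tuple(crops)


def crop_field(field: np.ndarray, crops) -> np.ndarray:
    return field[(slice(None),) + tuple(crops)]


def normalize_volume(data: np.ndarray) -> np.ndarray:
    """Min-max normalize intensities to [0, 1] (constant volumes map to 0)."""
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 0:
        return np.zeros_like(data, dtype=np.float32)
    return ((data - lo) / (hi - lo)).astype(np.float32)


# ---------------------------------------------------------------------------
# Multi-resolution forward pass
# ---------------------------------------------------------------------------

@dataclass
class MultiResState:
    """Everything one coarse-to-fine forward pass produces."""

    svfs: list          # incremental v_l tensors, coarse to fine
    vtildes: list       # accumulated v~_l tensors on each level's grid
    warped_inputs: list  # full-res moving image fed to each sub-network
    forward_field: Tensor
    inverse_field: Tensor


def forward_multires(fixed: np.ndarray, moving: np.ndarray,
                     nets: list[Subnetwork], steps: int = DEFAULT_STEPS,
                     sigma: float = DEFAULT_SIGMA, ksize: int = DEFAULT_KSIZE,
                     smooth_final: bool = True,
                     final_fields: bool = True) -> MultiResState:
    """Run the coarse-to-fine cascade on a normalized, /16-divisible pair.

    The coarsest sub-network sees (moving, fixed); each finer one sees the
    moving image warped at full resolution by the integrated accumulated
    velocity of the preceding levels, concatenated with the fixed image.
    The final forward/inverse displacements integrate +/- v~_L upsampled to
    the full grid, with the Gaussian smoothing layer applied at the end.
    """
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    if any(s % 16 for s in fixed.shape):
        raise ValueError(f"shape {fixed.shape} not divisible by 16; pad first")
    full_shape = fixed.shape
    f_img = Tensor(fixed[None])
    m_img = Tensor(moving[None])

    svfs, vtildes, warped_inputs = [], [], []
    vtilde = None
    current_m = m_img
    for net in nets:
        warped_inputs.append(current_m)
        x = ad.concat([current_m, f_img], axis=0)
        v_l = net.forward(x)
        svfs.append(v_l)
        if vtilde is None:
            vtilde = v_l
        else:
            vtilde = core.upsample_t(vtilde, v_l.shape[1:]) + v_l
        vtildes.append(vtilde)
        if net is not nets[-1]:
            u = core.integrate_svf_t(core.upsample_t(vtilde, full_shape), steps)
            current_m = core.warp_t(m_img, u)

    u_fwd = u_inv = None
    if final_fields:
        v_full = core.upsample_t(vtilde, full_shape)
        u_fwd = core.integrate_svf_t(v_full, steps)
        u_inv = core.integrate_svf_t(-v_full, steps)
        if smooth_final:
            u_fwd = core.gaussian_smooth_t(u_fwd, sigma, ksize)
            u_inv = core.gaussian_smooth_t(u_inv, sigma, ksize)
    return MultiResState(svfs=svfs, vtildes=vtildes, warped_inputs=warped_inputs,
                         forward_field=u_fwd, inverse_field=u_inv)
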