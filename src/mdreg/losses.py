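"""Similarity and regularization terms for self-supervised registration.

The training objective maximizes normalized cross-correlation (NCC) between
each fixed image and the warped moving image — in both directions, since a
stationary velocity field yields the inverse deformation by negation — and
penalizes the total variation (L1 norm of forward differences) of each
incremental velocity field:

    loss = sum_l [ -NCC(I_f^l, I_m^l o Phi(+v~_l))
                   -NCC(I_m^l, I_f^l o Phi(-v~_l))
                   + lambda * TV(v_l) ]

where v~_l is the accumulated velocity at level l (coarse to fine) and the
finest-level deformation additionally passes through the Gaussian smoothing
layer. NCC defaults to the local windowed form standard for this family of
methods (window 9^3), with a global Pearson option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import core
from .core import DEFAULT_SIGMA, DEFAULT_KSIZE, DEFAULT_STEPS

__all__ = ["LossConfig", "LossBreakdown", "ncc", "ncc_t", "tv_regularizer",
           "tv_t", "multires_loss"]

_EPS = 1e-5  # added to variance products before the square root


@dataclass
class LossConfig:
    """Weights and options of the multi-resolution objective."""

    lam: float = 0.35            # similarity/regularity trade-off
    ncc_window: int | str = 9    # odd window size, or "global"
    levels: int = 3              # number of velocity-field levels
    steps: int = DEFAULT_STEPS
    sigma: float = DEFAULT_SIGMA
    ksize: int = DEFAULT_KSIZE
    smooth_final: bool = True    # Gaussian smoothing layer at finest level
    full_res_term: bool = True   # supervise the full-resolution warp too

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lambda must be non-negative, got {self.lam}")
        if self.ncc_window != "global":
            w = int(self.ncc_window)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"ncc_window must be odd or 'global', got {w}")
            self.ncc_window = w


@dataclass
class LossBreakdown:
    """Per-level terms of one loss evaluation; ``total`` is the objective."""

    per_level_similarity_fwd: list = field(default_factory=list)
    per_level_similarity_inv: list = field(default_factory=list)
    per_level_tv: list = field(default_factory=list)
    lam: float = 0.0
    total: float = 0.0

    def as_row(self) -> dict:
        row = {"total": self.total}
        for i, v in enumerate(self.per_level_similarity_fwd, 1):
            row[f"sim_fwd_{i}"] = v
        for i, v in enumerate(self.per_level_similarity_inv, 1):
            row[f"sim_inv_{i}"] = v
        for i, v in enumerate(self.per_level_tv, 1):
            row[f"tv_{i}"] = v
        return row


# ---------------------------------------------------------------------------
# NCC
# ---------------------------------------------------------------------------

def _box_kernel(w: int) -> np.ndarray:
    return np.full(w, 1.0 / w, dtype=np.float32)


def ncc_t(a: Tensor, b: Tensor, window: int | str = 9) -> Tensor:
    """Differentiable NCC of two (1, D, H, W) or (D, H, W)-shaped tensors.

    Global mode is the Pearson correlation over all voxels; windowed mode is
    the mean over voxels of local zero-normalized cross-correlation computed
    with box filters (replicate borders).
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.data.ndim == 3:
        a = _reshape_channel(a)
        b = _reshape_channel(b)
    if window == "global":
        ma, mb = a.mean(), b.mean()
        da, db = a - ma, b - mb
        cov = (da * db).mean()
        va, vb = (da * da).mean(), (db * db).mean()
        return cov / ad.sqrt(va * vb + _EPS)
    w = int(window)
    k = _box_kernel(w)
    n_win = float(w) ** 3

    def box(x):
        for axis in (1, 2, 3):
            x = ad.conv1d_axis(x, k, axis)
        return x

    # window sums (means scaled by the window volume), the standard
    # formulation: the eps guard is then negligible except for flat windows
    ma, mb = box(a), box(b)
    cross = (box(a * b) - ma * mb) * n_win
    va = ad.relu(box(a * a) - ma * ma) * n_win
    vb = ad.relu(box(b * b) - mb * mb) * n_win
    cc = cross / ad.sqrt(va * vb + _EPS)
    return cc.mean()


def _reshape_channel(x: Tensor) -> Tensor:
    data = x.data.reshape((1,) + x.data.shape)

    def bw(g):
        x._accum(g.reshape(x.data.shape))

    out = Tensor(data, requires_grad=x.requires_grad, parents=(x,), backward=bw)
    return out if x.requires_grad else Tensor(data)


def ncc(a: core.Volume, b: core.Volume, window: int | str = 9) -> float:
    """NCC between two volumes; see :func:`ncc_t`."""
    return float(ncc_t(Tensor(a.data), Tensor(b.data), window).data)


# ---------------------------------------------------------------------------
# Total-variation regularizer
# ---------------------------------------------------------------------------

def tv_t(v: Tensor, spacing: float = 1.0) -> Tensor:
    """Mean (over voxels) L1 norm of forward differences of a (3,D,H,W) field.

    The penalty is the per-voxel, per-component mean of |d v_c / d x_a|
    summed over the three spatial axes. ``spacing`` is the grid step in
    full-resolution voxel units: velocity values are stored in
    full-resolution units at every level, so dividing the per-sample
    differences by the step keeps the gradient estimate — and hence the
    weight lambda — comparable across resolutions.
    """
    n = int(np.prod(v.shape))  # voxels x components
    total = None
    for axis in (1, 2, 3):
        term = ad.forward_diff(v, axis).abs().sum()
        total = term if total is None else total + term
    return total * (1.0 / (n * spacing))


def tv_regularizer(v: core.VelocityField, spacing: float = 1.0) -> float:
    return float(tv_t(Tensor(v.data), spacing).data)


# ---------------------------------------------------------------------------
# Multi-resolution bidirectional assembly
# ---------------------------------------------------------------------------

def multires_loss(pyr_f: list, pyr_m: list, svfs: list[Tensor],
                  cfg: LossConfig) -> tuple[Tensor, LossBreakdown]:
    """Assemble the deep-supervision objective from per-level incremental SVFs.

    ``pyr_f`` / ``pyr_m`` are pyramids ordered coarse to fine with
    ``cfg.levels + 1`` entries: the first ``levels`` grids host the velocity
    levels (1/8, 1/4, 1/2 for levels=3) and the last is the full-resolution
    image pair. ``svfs`` are the incremental velocities v_l as tensors on
    those grids, in full-resolution voxel units. Returns the scalar loss
    tensor and a float breakdown.

    Per level the accumulated velocity is integrated in both directions
    (scaling and squaring) and similarity is measured on that level's
    pyramid images; the full-resolution term applies the Gaussian smoothing
    layer to the displacement first. The TV penalty acts on each incremental
    v_l on its native grid.
    """
    L = cfg.levels
    if len(svfs) != L:
        raise ValueError(f"expected {L} velocity levels, got {len(svfs)}")
    if len(pyr_f) < L + 1 or len(pyr_m) < L + 1:
        raise ValueError("pyramids must provide one grid per level plus full res")

    full_shape = _vol_data(pyr_f[-1]).shape
    bd = LossBreakdown(lam=cfg.lam)
    total = None

    vtilde = None
    for l in range(L):
        v_l = svfs[l]
        grid = v_l.shape[1:]
        vtilde = v_l if vtilde is None else core.upsample_t(vtilde, grid) + v_l

        scale = full_shape[0] / grid[0]  # full-res units -> this grid's units
        f_img = Tensor(_vol_data(pyr_f[l])[None])
        m_img = Tensor(_vol_data(pyr_m[l])[None])
        sim_f, sim_m = _bidirectional_similarity(
            f_img, m_img, vtilde * (1.0 / scale), cfg, smooth=False)
        tv_l = tv_t(v_l, spacing=scale)

        bd.per_level_similarity_fwd.append(float(sim_f.data))
        bd.per_level_similarity_inv.append(float(sim_m.data))
        bd.per_level_tv.append(float(tv_l.data))
        term = -sim_f - sim_m + cfg.lam * tv_l
        total = term if total is None else total + term

    if cfg.full_res_term:
        v_full = core.upsample_t(vtilde, full_shape)
        f_img = Tensor(_vol_data(pyr_f[-1])[None])
        m_img = Tensor(_vol_data(pyr_m[-1])[None])
        sim_f, sim_m = _bidirectional_similarity(
            f_img, m_img, v_full, cfg, smooth=cfg.smooth_final)
        bd.per_level_similarity_fwd.append(float(sim_f.data))
        bd.per_level_similarity_inv.append(float(sim_m.data))
        total = total - sim_f - sim_m

    bd.total = float(total.data)
    return total, bd


def _bidirectional_similarity(f_img: Tensor, m_img: Tensor, v: Tensor,
                              cfg: LossConfig, smooth: bool):
    u_fwd = core.integrate_svf_t(v, cfg.steps)
    u_inv = core.integrate_svf_t(-v, cfg.steps)
    if smooth:
        u_fwd = core.gaussian_smooth_t(u_fwd, cfg.sigma, cfg.ksize)
        u_inv = core.gaussian_smooth_t(u_inv, cfg.sigma, cfg.ksize)
    warped_m = core.warp_t(m_img, u_fwd)
    warped_f = core.warp_t(f_img, u_inv)
    sim_f = ncc_t(f_img, warped_m, cfg.ncc_window)
    sim_m = ncc_t(m_img, warped_f, cfg.ncc_window)
    return sim_f, sim_m


def _vol_data(v) -> np.ndarray:
    if isinstance(v, np.ndarray):
        return v
    return np.asarray(v.data if isinstance(v, (core.Volume, Tensor)) else v,
                      dtype=np.float32)
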