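"""Geometric primitives against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from mdreg.core import (Volume, VelocityField, DisplacementField, LabelMap,
                        avg_pool3, build_pyramid, compose_displacements,
                        gaussian_kernel1d, gaussian_smooth_field, identity_grid,
                        integrate_svf, jacobian_determinant, upsample_field,
                        warp_volume)


# ---------------------------------------------------------------------------
# Pyramid
# ---------------------------------------------------------------------------

class TestPyramid:
    def test_constant_volume_is_constant_at_every_level(self):
        pyr = build_pyramid(Volume(np.full((16, 16, 16), 3.25, np.float32)), 3)
        assert len(pyr) == 3
        for vol in pyr:
            np.testing.assert_allclose(vol.data, 3.25, rtol=1e-6)

    def test_paper_scale_level_shapes(self):
        vol = Volume(np.zeros((176, 192, 176), np.float32))
        shapes = [p.shape for p in build_pyramid(vol, 4)]
        assert shapes == [(22, 24, 22), (44, 48, 44), (88, 96, 88),
                          (176, 192, 176)]

    def test_single_pooling_matches_window_mean_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 4, 4)).astype(np.float32)
        out = avg_pool3(x)
        xp = np.pad(x, 1, mode="edge")
        for i, j, k in itertools.product(range(2), repeat=3):
            expect = xp[2 * i:2 * i + 3, 2 * j:2 * j + 3, 2 * k:2 * k + 3].mean()
            assert out[i, j, k] == pytest.approx(expect, abs=1e-6)

    def test_finest_level_is_original(self):
        rng = np.random.default_rng(1)
        vol = Volume(rng.random((16, 16, 16)).astype(np.float32))
        pyr = build_pyramid(vol, 3)
        np.testing.assert_array_equal(pyr[-1].data, vol.data)

    def test_rejects_bad_levels_and_shapes(self):
        vol = Volume(np.zeros((16, 16, 16), np.float32))
        with pytest.raises(ValueError):
            build_pyramid(vol, 0)
        with pytest.raises(ValueError):
            build_pyramid(Volume(np.zeros((18, 16, 16), np.float32)), 3)


# ---------------------------------------------------------------------------
# SVF integration
# ---------------------------------------------------------------------------

def euler_flow(v: np.ndarray, n_steps: int) -> np.ndarray:
    """Explicit Euler integration of dD/dt = v(D), an independent oracle."""
    grid = identity_grid(v.shape[1:]).astype(np.float64)
    u = np.zeros_like(grid)
    dt = 1.0 / n_steps
    for _ in range(n_steps):
        x = grid + u
        vx = np.stack([map_coordinates(v[c].astype(np.float64), x, order=1,
                                       mode="nearest") for c in range(3)])
        u = u + dt * vx
    return u


class TestIntegrateSvf:
    def test_zero_velocity_gives_identity(self):
        u = integrate_svf(VelocityField(np.zeros((3, 8, 8, 8), np.float32)))
        assert np.abs(u.data).max() == 0

    def test_matches_euler_oracle(self, smooth_svf24):
        u = integrate_svf(smooth_svf24, steps=7)
        ref = euler_flow(smooth_svf24.data, 1024)
        m = 3  # interior margin, voxels
        err = np.abs(u.data - ref)[:, m:-m, m:-m, m:-m].max()
        assert err < 0.05

    def test_step_refinement_converges(self, smooth_svf24):
        m = 3
        ref = euler_flow(smooth_svf24.data, 1024)[:, m:-m, m:-m, m:-m]
        e7 = np.abs(integrate_svf(smooth_svf24, 7).data[:, m:-m, m:-m, m:-m]
                    - ref).max()
        e10 = np.abs(integrate_svf(smooth_svf24, 10).data[:, m:-m, m:-m, m:-m]
                     - ref).max()
        assert e10 <= e7 + 1e-4

    def test_rejects_nonpositive_steps(self, smooth_svf24):
        with pytest.raises(ValueError):
            integrate_svf(smooth_svf24, steps=0)


# ---------------------------------------------------------------------------
# Composition / warping
# ---------------------------------------------------------------------------

class TestCompose:
    def test_identity_inner_and_outer(self):
        rng = np.random.default_rng(3)
        u = DisplacementField(rng.standard_normal((3, 8, 8, 8)).astype(np.float32))
        zero = DisplacementField(np.zeros((3, 8, 8, 8), np.float32))
        np.testing.assert_allclose(compose_displacements(u, zero).data, u.data,
                                   atol=1e-5)
        np.testing.assert_allclose(compose_displacements(zero, u).data, u.data,
                                   atol=1e-5)

    def test_translations_add_in_interior(self):
        shape = (3, 12, 12, 12)
        a = np.zeros(shape, np.float32)
        a[0] = 2.0
        b = np.zeros(shape, np.float32)
        b[1] = 1.0
        r = compose_displacements(DisplacementField(a), DisplacementField(b))
        interior = r.data[:, 3:-3, 3:-3, 3:-3].reshape(3, -1)
        np.testing.assert_allclose(interior.mean(axis=1), [2.0, 1.0, 0.0],
                                   atol=1e-5)

    def test_shape_mismatch_rejected(self):
        a = DisplacementField(np.zeros((3, 8, 8, 8), np.float32))
        b = DisplacementField(np.zeros((3, 6, 6, 6), np.float32))
        with pytest.raises(ValueError):
            compose_displacements(a, b)


class TestWarpVolume:
    def test_zero_displacement_is_identity(self, phantom32):
        vol, labels = phantom32
        u = DisplacementField(np.zeros((3,) + vol.shape, np.float32))
        np.testing.assert_allclose(warp_volume(vol, u).data, vol.data, atol=1e-5)
        np.testing.assert_array_equal(warp_volume(labels, u, "nearest").data,
                                      labels.data)

    def test_integer_translation_matches_index_shift(self, phantom32):
        vol, _ = phantom32
        u = np.zeros((3,) + vol.shape, np.float32)
        u[0] = 2.0
        out = warp_volume(vol, DisplacementField(u)).data
        np.testing.assert_allclose(out[:-2], vol.data[2:], atol=1e-5)

    def test_nearest_mode_preserves_label_set(self, pair32):
        _, _, labels_f, labels_m, _ = pair32
        assert set(np.unique(labels_m.data)) <= set(np.unique(labels_f.data))

    def test_unknown_mode_rejected(self, phantom32):
        vol, _ = phantom32
        u = DisplacementField(np.zeros((3,) + vol.shape, np.float32))
        with pytest.raises(ValueError):
            warp_volume(vol, u, mode="cubic")


# ---------------------------------------------------------------------------
# Field upsampling
# ---------------------------------------------------------------------------

class TestUpsampleField:
    def test_constant_field_stays_constant(self):
        f = VelocityField(np.full((3, 4, 4, 4), 1.5, np.float32))
        out = upsample_field(f, (9, 9, 9))
        np.testing.assert_allclose(out.data, 1.5, atol=1e-6)

    def test_linear_ramp_midpoints_are_means(self):
        data = np.zeros((3, 2, 2, 2), np.float32)
        data[0] = np.arange(2, dtype=np.float32)[:, None, None]
        out = upsample_field(VelocityField(data), (3, 3, 3))
        np.testing.assert_allclose(out.data[0, :, 0, 0], [0.0, 0.5, 1.0],
                                   atol=1e-6)

    def test_refinement_reproduces_nodes(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((3, 5, 5, 5)).astype(np.float32)
        out = upsample_field(DisplacementField(data), (9, 9, 9))
        np.testing.assert_allclose(out.data[:, ::2, ::2, ::2], data, atol=1e-5)

    def test_shrinking_rejected(self):
        f = VelocityField(np.zeros((3, 8, 8, 8), np.float32))
        with pytest.raises(ValueError):
            upsample_field(f, (4, 8, 8))


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------

class TestGaussianSmooth:
    def test_constant_field_unchanged(self):
        u = DisplacementField(np.full((3, 8, 8, 8), 2.5, np.float32))
        np.testing.assert_allclose(gaussian_smooth_field(u).data, 2.5, atol=1e-5)

    def test_impulse_matches_kernel_outer_product(self):
        u = np.zeros((3, 9, 9, 9), np.float32)
        u[1, 4, 4, 4] = 1.0
        out = gaussian_smooth_field(DisplacementField(u), sigma=1.732, ksize=3)
        k = gaussian_kernel1d(1.732, 3)
        expect = k[:, None, None] * k[None, :, None] * k[None, None, :]
        np.testing.assert_allclose(out.data[1, 3:6, 3:6, 3:6], expect, atol=1e-6)
        assert np.abs(out.data[0]).max() == 0  # channels independent

    def test_even_kernel_rejected(self):
        u = DisplacementField(np.zeros((3, 8, 8, 8), np.float32))
        with pytest.raises(ValueError):
            gaussian_smooth_field(u, ksize=4)


# ---------------------------------------------------------------------------
# Jacobian determinant
# ---------------------------------------------------------------------------

def jacobian_oracle(u: np.ndarray) -> np.ndarray:
    """Voxel-by-voxel 3x3 finite-difference determinant (slow, explicit)."""
    D, H, W = u.shape[1:]
    out = np.zeros((D, H, W))

    def deriv(c, axis, idx):
        i = list(idx)
        n = u.shape[1 + axis]
        if idx[axis] == 0:
            i[axis] = 1
            hi = u[(c, *i)]
            i[axis] = 0
            return hi - u[(c, *i)]
        if idx[axis] == n - 1:
            i[axis] = n - 1
            hi = u[(c, *i)]
            i[axis] = n - 2
            return hi - u[(c, *i)]
        i[axis] = idx[axis] + 1
        hi = u[(c, *i)]
        i[axis] = idx[axis] - 1
        return (hi - u[(c, *i)]) / 2.0

    for idx in itertools.product(range(D), range(H), range(W)):
        J = np.eye(3)
        for a in range(3):
            for b in range(3):
                J[a, b] += deriv(a, b, idx)
        out[idx] = np.linalg.det(J)
    return out


class TestJacobian:
    def test_identity_map_has_unit_determinant(self):
        u = DisplacementField(np.zeros((3, 8, 8, 8), np.float32))
        np.testing.assert_allclose(jacobian_determinant(u).data, 1.0, atol=1e-6)

    def test_global_scaling_gives_cubed_factor(self):
        s = 1.1
        g = identity_grid((8, 8, 8))
        u = DisplacementField(((s - 1) * g).astype(np.float32))
        det = jacobian_determinant(u).data
        np.testing.assert_allclose(det[2:-2, 2:-2, 2:-2], s ** 3, rtol=1e-4)

    def test_matches_per_voxel_oracle(self, smooth_field_factory):
        rng = np.random.default_rng(9)
        v = smooth_field_factory(rng, (16, 16, 16), 2.0)
        det = jacobian_determinant(DisplacementField(v)).data
        np.testing.assert_allclose(det, jacobian_oracle(v.astype(np.float64)),
                                   atol=1e-4)

    def test_small_grids_rejected(self):
        with pytest.raises(ValueError):
            jacobian_determinant(DisplacementField(np.zeros((3, 2, 8, 8),
                                                            np.float32)))


# ---------------------------------------------------------------------------
# Cross-cutting invariants
# ---------------------------------------------------------------------------

class TestFlowInvariants:
    def test_inverse_consistency_of_integration(self, smooth_svf24):
        fwd = integrate_svf(smooth_svf24)
        inv = integrate_svf(VelocityField(-smooth_svf24.data))
        resid = compose_displacements(inv, fwd).data
        m = 3
        norms = np.linalg.norm(resid[:, m:-m, m:-m, m:-m], axis=0)
        assert norms.mean() < 0.1

    def test_integration_is_fold_free_for_smooth_field(self, smooth_svf24):
        det = jacobian_determinant(integrate_svf(smooth_svf24)).data
        assert det.min() > 0
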