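"""Similarity and regularization terms against direct-formula oracles."""

import numpy as np
import pytest

from mdreg.autodiff import Tensor
from mdreg.core import (Volume, VelocityField, gaussian_smooth_t,
                        integrate_svf_t, upsample_t, warp_t)
from mdreg.losses import (LossConfig, multires_loss, ncc, ncc_t, tv_regularizer,
                          tv_t)


def _texture(shape, seed=0, lo=0.0, hi=4.0):
    rng = np.random.default_rng(seed)
    return Volume(rng.uniform(lo, hi, shape).astype(np.float32))


class TestNcc:
    @pytest.mark.parametrize("window", ["global", 9])
    def test_self_similarity_is_one(self, window):
        img = _texture((12, 12, 12))
        assert ncc(img, img, window) == pytest.approx(1.0, abs=1e-3)

    def test_affine_intensity_invariance_global(self):
        img = _texture((10, 10, 10), seed=1)
        up = Volume(2.5 * img.data + 3.0)
        down = Volume(-1.5 * img.data + 10.0)
        assert ncc(img, up, "global") == pytest.approx(1.0, abs=1e-4)
        assert ncc(img, down, "global") == pytest.approx(-1.0, abs=1e-4)

    def test_global_matches_pearson_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.random((8, 8, 8)).astype(np.float32) * 5
        b = (0.5 * a + rng.random((8, 8, 8)).astype(np.float32)).astype(np.float32)
        va, vb = a - a.mean(), b - b.mean()
        expect = (va * vb).mean() / np.sqrt((va ** 2).mean() * (vb ** 2).mean()
                                            + 1e-5)
        assert ncc(Volume(a), Volume(b), "global") == pytest.approx(
            float(expect), abs=1e-6)

    def test_constant_input_guarded(self):
        flat = Volume(np.full((8, 8, 8), 2.0, np.float32))
        img = _texture((8, 8, 8), seed=3)
        assert abs(ncc(flat, img, "global")) < 1e-3

    def test_bounded_in_unit_interval(self):
        a = _texture((10, 10, 10), seed=4)
        b = _texture((10, 10, 10), seed=5)
        for window in ("global", 5, 9):
            assert -1.0 - 1e-5 <= ncc(a, b, window) <= 1.0 + 1e-5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ncc_t(Tensor(np.zeros((8, 8, 8), np.float32)),
                  Tensor(np.zeros((6, 6, 6), np.float32)))


class TestTvRegularizer:
    def test_constant_field_has_zero_tv(self):
        v = VelocityField(np.full((3, 8, 8, 8), 4.2, np.float32))
        assert tv_regularizer(v) == 0.0

    def test_unit_ramp_matches_loop_oracle(self):
        data = np.zeros((3, 8, 8, 8), np.float32)
        data[0] = np.arange(8, dtype=np.float32)[:, None, None]
        v = VelocityField(data)
        # direct summation: |forward difference|, last slice zero, mean over
        # all voxel-component samples
        total = 0.0
        for c in range(3):
            for ax in range(3):
                d = np.abs(np.diff(data[c], axis=ax))
                total += d.sum()
        expect = total / (3 * 8 ** 3)
        assert tv_regularizer(v) == pytest.approx(expect, abs=1e-6)

    def test_absolute_homogeneity(self):
        rng = np.random.default_rng(6)
        v = rng.standard_normal((3, 6, 6, 6)).astype(np.float32)
        base = tv_regularizer(VelocityField(v))
        assert tv_regularizer(VelocityField(-2.0 * v)) == pytest.approx(
            2.0 * base, rel=1e-5)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(7)
        v = rng.standard_normal((3, 6, 6, 6)).astype(np.float32)
        assert tv_regularizer(VelocityField(v + 3.0)) == pytest.approx(
            tv_regularizer(VelocityField(v)), rel=1e-4)

    def test_spacing_scales_gradient_estimate(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal((3, 6, 6, 6)).astype(np.float32)
        assert tv_regularizer(VelocityField(v), spacing=2.0) == pytest.approx(
            tv_regularizer(VelocityField(v)) / 2.0, rel=1e-5)


class TestMultiresLoss:
    def _pyramids(self, img: np.ndarray, levels: int):
        from mdreg.core import build_pyramid

        return [v.data for v in build_pyramid(Volume(img), levels + 1)]

    def test_identity_registration_saturates_similarity(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(0, 4, (32, 32, 32)).astype(np.float32)
        pyr = self._pyramids(img, 3)
        svfs = [Tensor(np.zeros((3, s, s, s), np.float32), requires_grad=True)
                for s in (4, 8, 16)]
        cfg = LossConfig(lam=0.35, levels=3, full_res_term=True)
        total, bd = multires_loss(pyr, pyr, svfs, cfg)
        for sim in bd.per_level_similarity_fwd + bd.per_level_similarity_inv:
            assert sim == pytest.approx(1.0, abs=5e-3)
        assert all(t == 0 for t in bd.per_level_tv)
        assert bd.total == pytest.approx(-2 * len(bd.per_level_similarity_fwd),
                                         abs=0.05)

    def test_lambda_zero_total_is_negative_similarity_sum(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(0, 4, (16, 16, 16)).astype(np.float32)
        b = rng.uniform(0, 4, (16, 16, 16)).astype(np.float32)
        svfs = [Tensor(0.3 * rng.standard_normal((3, s, s, s)).astype(np.float32),
                       requires_grad=True) for s in (2, 4, 8)]
        cfg = LossConfig(lam=0.0, levels=3)
        total, bd = multires_loss(self._pyramids(a, 3), self._pyramids(b, 3),
                                  svfs, cfg)
        expect = -sum(bd.per_level_similarity_fwd) - sum(bd.per_level_similarity_inv)
        assert bd.total == pytest.approx(expect, abs=1e-5)

    def test_single_level_matches_hand_assembled_chain(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 4, (16, 16, 16)).astype(np.float32)
        b = rng.uniform(0, 4, (16, 16, 16)).astype(np.float32)
        v = Tensor(0.5 * rng.standard_normal((3, 8, 8, 8)).astype(np.float32),
                   requires_grad=True)
        cfg = LossConfig(lam=0.35, levels=1, full_res_term=False, ncc_window=9)
        total, bd = multires_loss(self._pyramids(a, 1), self._pyramids(b, 1),
                                  [v], cfg)

        # independent assembly from the public primitives
        pyr_a = self._pyramids(a, 1)
        pyr_b = self._pyramids(b, 1)
        scale = 2.0  # level grid is half the full grid
        u_f = integrate_svf_t(v * (1 / scale), 7)
        u_i = integrate_svf_t(v * (-1 / scale), 7)
        wm = warp_t(Tensor(pyr_b[0][None]), u_f)
        wf = warp_t(Tensor(pyr_a[0][None]), u_i)
        sim_f = float(ncc_t(Tensor(pyr_a[0][None]), wm, 9).data)
        sim_i = float(ncc_t(Tensor(pyr_b[0][None]), wf, 9).data)
        tv = float(tv_t(v, spacing=scale).data)
        assert bd.total == pytest.approx(-sim_f - sim_i + 0.35 * tv, abs=1e-5)

    def test_level_count_mismatch_rejected(self):
        cfg = LossConfig(levels=3)
        with pytest.raises(ValueError):
            multires_loss([np.zeros((4, 4, 4), np.float32)] * 4,
                          [np.zeros((4, 4, 4), np.float32)] * 4,
                          [Tensor(np.zeros((3, 4, 4, 4), np.float32))] * 2, cfg)

    def test_gradient_descent_on_velocity_reduces_loss(self, pair32):
        from mdreg.training import Adam, TrainConfig, _Prepared

        fixed, moving = pair32[0], pair32[1]
        pf, pm = _Prepared(fixed, 3), _Prepared(moving, 3)
        cfg = TrainConfig(lam=0.35, iterations=1).loss_config()
        svfs = [Tensor(np.zeros((3, s, s, s), np.float32), requires_grad=True)
                for s in (4, 8, 16)]
        opt = Adam(svfs, lr=0.1)
        first = None
        for _ in range(25):
            opt.zero_grad()
            loss, bd = multires_loss(pf.pyramid, pm.pyramid, svfs, cfg)
            if first is None:
                first = bd.total
            loss.backward()
            opt.step()
        assert bd.total < first
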