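"""Similarity and regularization losses: closed forms, brute-force windowed
NCC oracle, degenerate inputs, and differentiability."""

import numpy as np
import pytest

from wavemorph.autodiff import Tensor
from wavemorph.objectives import (LossConfig, diffusion_reg, lncc_loss,
                                  mse_loss, total_loss)


def brute_force_lncc(f, w, n):
    """Direct per-voxel windowed NCC, averaged over the volume."""
    h = n // 2
    shape = f.shape
    total = 0.0
    f = f.astype(np.float64)
    w = w.astype(np.float64)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                fw = f[max(0, i - h):i + h + 1, max(0, j - h):j + h + 1,
                       max(0, k - h):k + h + 1]
                ww = w[max(0, i - h):i + h + 1, max(0, j - h):j + h + 1,
                       max(0, k - h):k + h + 1]
                fc = fw - fw.mean()
                wc = ww - ww.mean()
                denom = np.sqrt((fc ** 2).sum() * (wc ** 2).sum() + 1e-5)
                total += (fc * wc).sum() / denom
    return -total / f.size


class TestMSE:
    def test_zero_on_equal(self, rng):
        f = rng.standard_normal((6, 6, 6)).astype(np.float32)
        assert mse_loss(f, f) == 0.0

    def test_unit_difference(self):
        assert mse_loss(np.ones((4, 4, 4)), np.zeros((4, 4, 4))) == 1.0

    def test_two_voxel_toy(self):
        f = np.array([[[0.0, 2.0]]])
        w = np.zeros((1, 1, 2))
        assert mse_loss(f, w) == pytest.approx(2.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)))


class TestLNCC:
    def test_self_correlation_is_one(self, rng):
        f = rng.random((12, 12, 12)).astype(np.float32)
        assert lncc_loss(f, f, 9) == pytest.approx(-1.0, abs=1e-4)

    def test_affine_intensity_invariance(self, rng):
        f = rng.random((12, 12, 12)).astype(np.float32)
        assert lncc_loss(f, 2.0 * f + 0.5, 9) == pytest.approx(-1.0, abs=1e-4)

    def test_negated_image_anticorrelates(self, rng):
        f = rng.standard_normal((8, 8, 8)).astype(np.float32)
        f -= f.mean()
        assert lncc_loss(f, -f, 5) == pytest.approx(1.0, abs=1e-4)

    def test_matches_brute_force_window_oracle(self, rng):
        f = rng.standard_normal((8, 8, 8)).astype(np.float32)
        w = rng.standard_normal((8, 8, 8)).astype(np.float32)
        ours = lncc_loss(f, w, 5)
        ref = brute_force_lncc(f - f.mean(), w - w.mean(), 5)
        assert ours == pytest.approx(ref, abs=2e-3)

    def test_constant_images_are_defined(self):
        f = np.full((8, 8, 8), 0.7, np.float32)
        val = lncc_loss(f, f, 5)
        assert np.isfinite(val) and val == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self, rng):
        f = rng.random((8, 8, 8)).astype(np.float32)
        w = rng.random((8, 8, 8)).astype(np.float32)
        assert lncc_loss(f, w, 5) == pytest.approx(lncc_loss(w, f, 5), abs=1e-6)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            lncc_loss(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), 4)


class TestDiffusionReg:
    def test_zero_on_constant_field(self):
        u = np.full((3, 6, 6, 6), 3.7, np.float32)
        assert diffusion_reg(u) == 0.0

    def test_linear_ramp_closed_form(self):
        # u_x = s*i: one of the nine component-direction terms is s^2 on the
        # valid stencil, averaged over 3 components -> s^2/3
        s = 0.3
        u = np.zeros((3, 8, 8, 8), np.float32)
        u[0] = s * np.arange(8, dtype=np.float32).reshape(8, 1, 1)
        assert diffusion_reg(u) == pytest.approx(s * s / 3.0, rel=1e-5)

    def test_quadratic_homogeneity(self, rng):
        u = rng.standard_normal((3, 6, 6, 6)).astype(np.float32)
        assert diffusion_reg(2.0 * u) == pytest.approx(4.0 * diffusion_reg(u),
                                                       rel=1e-4)

    def test_matches_brute_force_stencil_sum(self, rng):
        u = rng.standard_normal((3, 8, 8, 8)).astype(np.float64)
        ref = 0.0
        for ax in range(3):
            d = np.diff(u, axis=1 + ax)
            ref += (d ** 2).mean()
        assert diffusion_reg(u.astype(np.float32)) == pytest.approx(ref, rel=1e-4)


class TestTotalLoss:
    def test_identity_pair_attains_minimum(self, rng):
        f = rng.random((8, 8, 8)).astype(np.float32)
        u = np.zeros((3, 8, 8, 8), np.float32)
        loss, sim, reg = total_loss(f, f, u, LossConfig(similarity="mse"))
        assert loss == 0.0 and reg == 0.0
        loss, _, _ = total_loss(f, f, u, LossConfig(similarity="ncc",
                                                    ncc_window=5))
        assert loss == pytest.approx(-1.0, abs=1e-4)

    def test_lambda_zero_is_similarity_alone(self, rng):
        f = rng.random((8, 8, 8)).astype(np.float32)
        m = rng.random((8, 8, 8)).astype(np.float32)
        u = rng.uniform(-1, 1, (3, 8, 8, 8)).astype(np.float32)
        cfg = LossConfig(similarity="mse", lam=0.0)
        loss, sim, _ = total_loss(f, m, u, cfg)
        assert loss == sim

    def test_regularizer_monotone_under_field_inflation(self, rng):
        u = rng.standard_normal((3, 8, 8, 8)).astype(np.float32)
        regs = [diffusion_reg(s * u) for s in (0.5, 1.0, 1.5, 2.0, 3.0)]
        assert all(a <= b for a, b in zip(regs, regs[1:]))

    def test_differentiable_with_respect_to_field(self, rng):
        f = rng.random((8, 8, 8)).astype(np.float32)
        m = rng.random((8, 8, 8)).astype(np.float32)
        for sim in ("mse", "ncc"):
            u = Tensor(rng.uniform(-1, 1, (1, 3, 8, 8, 8)).astype(np.float32),
                       requires_grad=True)
            cfg = LossConfig(similarity=sim, ncc_window=5)
            loss, _, _ = total_loss(Tensor(f[None, None]), Tensor(m[None, None]),
                                    u, cfg)
            loss.backward()
            assert np.isfinite(u.grad).all() and np.abs(u.grad).max() > 0


class TestLossConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(similarity="mutual_information")
        with pytest.raises(ValueError):
            LossConfig(ncc_window=8)
        with pytest.raises(ValueError):
            LossConfig(lam=-1.0)
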