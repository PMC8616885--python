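import numpy as np
import pytest

from tlct.classic import (IterativeConfig, fbp, iterative_reconstruct,
                          iterative_update, mean_correct, tv_grad, tv_norm, tv_step)
from tlct.evaluate import mae, roi_mask
from tlct.geometry import GeometryConfig, SensitivityProfile
from tlct.phantoms import shepp_logan
from tlct.projector import (Sinogram, WeightedSystem, unweighted_radon,
                            weighted_forward_project)


class TestFBP:
    def test_recovers_phantom_from_plain_radon(self):
        """Self-consistency at the reference discretization."""
        g = GeometryConfig()
        ph = shepp_logan(400)
        rec = fbp(unweighted_radon(ph, g))
        assert mae(rec, ph, roi_mask(g)) < 0.02

    def test_zero_sinogram_gives_zero_image(self, small_geometry):
        rec = fbp(Sinogram(np.zeros((45, 65)), small_geometry))
        np.testing.assert_allclose(rec, 0.0, atol=1e-14)

    def test_full_scan_averages_out_linear_sensitivity(self):
        """Over 2*pi the linear ramp averages to its iso-center value, so
        dividing the FBP image by that value recovers the phantom."""
        g = GeometryConfig(angular_range=2 * np.pi)
        prof = SensitivityProfile()
        ph = shepp_logan(400)
        rec = fbp(weighted_forward_project(ph, g, prof)) / prof.iso_center_weight
        assert mae(rec, ph, roi_mask(g)) < 0.02

    def test_shape_mismatch_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            fbp(Sinogram(np.zeros((45, 65)), small_geometry), GeometryConfig())


class TestMeanCorrect:
    def test_divides_by_iso_center_weight(self):
        prof = SensitivityProfile(s_min=0.1, s_max=0.9)
        img = np.full((4, 4), 3.0)
        np.testing.assert_allclose(mean_correct(img, prof), 6.0)

    def test_exact_for_constant_sensitivity(self, small_geometry):
        prof = SensitivityProfile(s_min=0.4, s_max=0.4, extent=65)
        ph = shepp_logan(65)
        rec = mean_correct(fbp(weighted_forward_project(ph, small_geometry, prof)), prof)
        plain = fbp(unweighted_radon(ph, small_geometry))
        np.testing.assert_allclose(rec, plain, atol=1e-9)

    def test_residual_ramp_artifact_persists_for_pi_scan(self):
        """A global rescale cannot remove the spatially varying artifact."""
        g = GeometryConfig(n_angles=100, n_detector=100, image_shape=(100, 100),
                          angle_offset=float(np.pi / 2))
        prof = SensitivityProfile(extent=100)
        ph = shepp_logan(100)
        rec = mean_correct(fbp(weighted_forward_project(ph, g, prof)), prof)
        err = rec - ph
        # artifact: signal too low on the left half, too high on the right
        left = err[30:70, 15:40].mean()
        right = err[30:70, 60:85].mean()
        assert left < -0.005 and right > 0.005


class TestTotalVariation:
    def test_constant_image_tv_is_epsilon_floor(self):
        # smoothed TV of a constant image equals eps * pixel count
        assert tv_norm(np.full((32, 32), 0.7)) == pytest.approx(1e-8 * 32 * 32, rel=1e-6)

    def test_square_matches_coarea_formula(self):
        """Analytic oracle: TV of an indicator = perimeter * jump height."""
        img = np.zeros((64, 64))
        img[20:40, 20:40] = 0.5  # 20x20 square, jump 0.5
        assert tv_norm(img) == pytest.approx(4 * 20 * 0.5, rel=0.03)

    def test_step_decreases_tv_on_noisy_image(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        stepped = tv_step(img, 1e-3)
        assert tv_norm(stepped) < tv_norm(img)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        img = rng.random((8, 8))
        g = tv_grad(img)
        eps = 1e-7
        for idx in [(0, 0), (3, 4), (7, 7), (5, 0)]:
            up = img.copy(); up[idx] += eps
            dn = img.copy(); dn[idx] -= eps
            fd = (tv_norm(up) - tv_norm(dn)) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)


@pytest.fixture(scope="module")
def tiny_system():
    g = GeometryConfig(n_angles=10, n_detector=12, image_shape=(9, 9))
    prof = SensitivityProfile(extent=9)
    return g, prof, WeightedSystem(g, prof)


class TestIterativeUpdate:
    def test_consistent_row_is_fixed_point(self, tiny_system):
        g, prof, system = tiny_system
        rng = np.random.default_rng(2)
        x = rng.random((9, 9))
        p = system.forward(x)
        for i in (0, 4, 9):
            x2 = iterative_update(x, i, system, step=1.0, sino_values=p)
            np.testing.assert_allclose(x2, x, atol=1e-12)

    def test_matches_dense_matrix_oracle(self, tiny_system):
        """Explicit dense implementation of the normalized row update."""
        g, prof, system = tiny_system
        dense = np.zeros((g.n_angles * g.n_detector, 81))
        for j in range(81):
            e = np.zeros(81)
            e[j] = 1.0
            dense[:, j] = system.forward(e.reshape(9, 9)).ravel()
        rng = np.random.default_rng(3)
        x = rng.random(81)
        target = rng.random((9, 9))
        p = system.forward(target)
        for i in (1, 5, 8):
            rows = dense[i * g.n_detector : (i + 1) * g.n_detector]
            norms = np.maximum((rows**2).sum(axis=1), 1e-12)
            expected = x + rows.T @ ((p[i] - rows @ x) / norms)
            got = iterative_update(x.reshape(9, 9), i, system, step=1.0, sino_values=p)
            np.testing.assert_allclose(got.ravel(), expected, atol=1e-8)

    def test_step_in_unit_interval_reduces_row_residual(self, tiny_system):
        g, prof, system = tiny_system
        rng = np.random.default_rng(4)
        x = rng.random((9, 9))
        p = system.forward(rng.random((9, 9)))
        for step in (0.25, 0.75, 1.0):
            for i in (0, 6):
                before = np.linalg.norm(p[i] - system.forward_one(x, i))
                x2 = iterative_update(x, i, system, step=step, sino_values=p)
                after = np.linalg.norm(p[i] - system.forward_one(x2, i))
                assert after <= before + 1e-12


class TestIterativeReconstruct:
    def test_constant_profile_noise_free_converges(self):
        """With constant sensitivity the system is well posed and the
        reconstruction approaches the phantom (TV step scaled to the small
        grid)."""
        g = GeometryConfig(n_angles=64, n_detector=64, image_shape=(64, 64))
        prof = SensitivityProfile(s_min=0.5, s_max=0.5, extent=64)
        ph = shepp_logan(64)
        sino = weighted_forward_project(ph, g, prof)
        cfg = IterativeConfig(n_iterations=150, tv_scale=4e-3)
        res = iterative_reconstruct(sino, None, prof, cfg)
        assert mae(res.image, ph, roi_mask(g)) < 0.01

    def test_weighted_system_needs_regularization(self, geometry64, profile64,
                                                  phantom64, weighted_sino64):
        """The weighted inverse problem is ill conditioned: the pure
        least-squares solution stalls away from the phantom, and the
        TV-regularized run beats both it and the uncorrected FBP."""
        plain = iterative_reconstruct(
            weighted_sino64, None, profile64,
            IterativeConfig(n_iterations=150, initial_lambda=0.0))
        reg = iterative_reconstruct(
            weighted_sino64, None, profile64,
            IterativeConfig(n_iterations=150, tv_scale=4e-3))
        mask = roi_mask(geometry64)
        mae_fbp = mae(fbp(weighted_sino64), phantom64, mask)
        mae_plain = mae(plain.image, phantom64, mask)
        mae_reg = mae(reg.image, phantom64, mask)
        assert mae_reg < mae_plain < mae_fbp

    def test_residual_trace_monotone_up_to_adaptation(self, geometry64, profile64,
                                                      weighted_sino64):
        cfg = IterativeConfig(n_iterations=40)
        res = iterative_reconstruct(weighted_sino64, None, profile64, cfg)
        tr = res.residual_trace
        assert len(tr) == 40
        # allow small equilibrium fluctuation, no sustained growth
        assert np.all(tr[1:] <= np.maximum.accumulate(tr)[:-1] * 1.10)
        assert tr[-1] < 0.5 * tr[0]

    def test_consistent_data_full_sweep_fixed_point(self):
        """Any x with B W x = p is unchanged by a sweep without TV."""
        g = GeometryConfig(n_angles=12, n_detector=16, image_shape=(11, 11))
        prof = SensitivityProfile(extent=11)
        rng = np.random.default_rng(5)
        x = rng.random((11, 11))
        sino = Sinogram(WeightedSystem(g, prof).forward(x), g)
        cfg = IterativeConfig(n_iterations=3, initial_lambda=0.0, init="zeros")
        # start from the consistent solution by replacing the init: emulate by
        # reconstructing from zeros and checking the solution stays put instead
        res = iterative_reconstruct(sino, None, prof, cfg)
        sys2 = WeightedSystem(g, prof)
        for i in range(g.n_angles):
            x2 = iterative_update(x, i, sys2, step=1.0, sino_values=sino.values)
            np.testing.assert_allclose(x2, x, atol=1e-10)
        assert np.all(np.isfinite(res.image))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            IterativeConfig(n_iterations=0)
        with pytest.raises(ValueError):
            IterativeConfig(initial_step=2.5)
        with pytest.raises(ValueError):
            IterativeConfig(initial_lambda=-0.1)
        with pytest.raises(ValueError):
            IterativeConfig(init="garbage")
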