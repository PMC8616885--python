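import numpy as np
import pytest

from tlct.geometry import GeometryConfig, SensitivityProfile, ramp_weight
from tlct.projector import (Sinogram, WeightedSystem, add_poisson_noise, row_norm,
                            unweighted_radon, weighted_backproject,
                            weighted_forward_project)


def _disk(n, radius, center=None):
    c = (n - 1) / 2 if center is None else center
    rows, cols = np.mgrid[0:n, 0:n]
    return (((rows - c) ** 2 + (cols - c) ** 2) <= radius**2).astype(float)


class TestForwardProjection:
    def test_zero_image_gives_zero_sinogram(self, small_geometry, small_profile):
        sino = weighted_forward_project(np.zeros((65, 65)), small_geometry, small_profile)
        assert np.all(sino.values == 0.0)

    def test_constant_profile_factors_out(self, small_geometry):
        """With S == c the weighted transform is c times the Radon transform."""
        rng = np.random.default_rng(0)
        img = rng.random((65, 65))
        prof = SensitivityProfile(s_min=0.37, s_max=0.37, extent=65)
        weighted = weighted_forward_project(img, small_geometry, prof)
        plain = unweighted_radon(img, small_geometry)
        np.testing.assert_allclose(weighted.values, 0.37 * plain.values, atol=1e-10)

    def test_central_impulse_sees_iso_center_weight(self):
        """A unit impulse at the rotation center projects to 0.5 * spacing.

        Exact for axis-aligned rays, where the unit-step samples coincide
        with the voxel lattice and only the central sample touches the
        impulse.
        """
        g = GeometryConfig(n_angles=4, angular_range=2 * np.pi, n_detector=65,
                          image_shape=(65, 65))
        prof = SensitivityProfile(extent=65)
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        sino = weighted_forward_project(img, g, prof)  # angles 0, pi/2, pi, 3pi/2
        np.testing.assert_allclose(sino.values[:, 32], 0.5, atol=1e-12)

    def test_matches_bruteforce_pixel_summation(self, small_profile):
        """Independent oracle: accumulate interpolated samples in pure numpy."""
        g = GeometryConfig(n_angles=7, n_detector=23, image_shape=(17, 17))
        prof = SensitivityProfile(extent=17)
        rng = np.random.default_rng(4)
        img = rng.random((17, 17))
        ours = weighted_forward_project(img, g, prof).values
        n = 17
        c = (n - 1) / 2
        L = 2 * int(np.ceil(0.5 * n * np.sqrt(2))) + 3
        sig = np.arange(L) - (L - 1) / 2
        w = ramp_weight(sig + (prof.extent - 1) / 2, prof)
        expected = np.zeros_like(ours)
        for i, th in enumerate(g.angles):
            for t in range(g.n_detector):
                tau = t - (g.n_detector - 1) / 2
                acc = 0.0
                for s in range(L):
                    x = c + sig[s] * np.cos(th) - tau * np.sin(th)
                    y = c + sig[s] * np.sin(th) + tau * np.cos(th)
                    x0, y0 = int(np.floor(x)), int(np.floor(y))
                    fx, fy = x - x0, y - y0
                    for dy, cy in ((0, 1 - fy), (1, fy)):
                        for dx, cx in ((0, 1 - fx), (1, fx)):
                            if 0 <= y0 + dy < n and 0 <= x0 + dx < n:
                                acc += cx * cy * w[s] * img[y0 + dy, x0 + dx]
                expected[i, t] = acc
        np.testing.assert_allclose(ours, expected, atol=1e-10)

    def test_linearity(self, small_geometry, small_profile):
        rng = np.random.default_rng(1)
        x, y = rng.random((2, 65, 65))
        fx = weighted_forward_project(x, small_geometry, small_profile).values
        fy = weighted_forward_project(y, small_geometry, small_profile).values
        fxy = weighted_forward_project(2.5 * x - 1.25 * y, small_geometry, small_profile).values
        np.testing.assert_allclose(fxy, 2.5 * fx - 1.25 * fy, atol=1e-9)

    def test_disk_profile_matches_chord_length(self, small_geometry):
        """Closed-form oracle: a unit disk projects to 2*sqrt(R^2 - t^2)."""
        R = 20.0
        sino = unweighted_radon(_disk(65, R), small_geometry)
        t = (np.arange(65) - 32.0)
        inside = np.abs(t) < R - 2
        expected = 2.0 * np.sqrt(np.clip(R**2 - t**2, 0, None))
        for i in (0, 10, 30):
            err = np.abs(sino.values[i, inside] - expected[inside])
            assert err.max() < 1.5  # discretized edge; chord length up to 40

    def test_centered_blob_rows_rotation_invariant(self, small_geometry):
        # a smooth radially symmetric object projects identically at every angle
        rows, cols = np.mgrid[0:65, 0:65]
        blob = np.exp(-(((rows - 32) ** 2 + (cols - 32) ** 2) / (2 * 8.0**2)))
        sino = unweighted_radon(blob, small_geometry)
        spread = sino.values.max(axis=0) - sino.values.min(axis=0)
        assert spread.max() < 5e-3 * sino.values.max()

    def test_shape_mismatch_rejected(self, small_geometry, small_profile):
        with pytest.raises(ValueError):
            weighted_forward_project(np.zeros((64, 64)), small_geometry, small_profile)

    def test_agrees_with_skimage_radon(self):
        """Independent oracle: scikit-image's Radon transform on a smooth blob."""
        from skimage.transform import radon

        n = 65
        rows, cols = np.mgrid[0:n, 0:n]
        img = np.exp(-(((rows - 32) / 9.0) ** 2 + ((cols - 36) / 7.0) ** 2))
        g = GeometryConfig(n_angles=12, angular_range=np.pi, n_detector=n,
                          image_shape=(n, n))
        ours = unweighted_radon(img, g).values
        # skimage: projection angle measured so that theta=0 integrates along
        # the vertical axis with the detector along x
        theirs = radon(img, theta=np.degrees(g.angles) + 90.0, circle=True).T
        rel = np.linalg.norm(ours - theirs) / np.linalg.norm(theirs)
        assert rel < 0.03


class TestAdjoint:
    def test_inner_product_identity(self, small_geometry, small_profile):
        rng = np.random.default_rng(2)
        system = WeightedSystem(small_geometry, small_profile)
        x = rng.standard_normal(small_geometry.image_shape)
        y = rng.standard_normal((small_geometry.n_angles, small_geometry.n_detector))
        lhs = np.sum(system.forward(x) * y)
        rhs = np.sum(x * system.adjoint(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_zero_sinogram_backprojects_to_zero(self, small_geometry, small_profile):
        sino = Sinogram(np.zeros((45, 65)), small_geometry)
        img = weighted_backproject(sino, small_geometry, small_profile)
        assert np.all(img == 0.0)

    def test_constant_profile_adjoint_scales(self, small_geometry):
        rng = np.random.default_rng(3)
        y = rng.random((45, 65))
        prof = SensitivityProfile(s_min=0.6, s_max=0.6, extent=65)
        weighted = WeightedSystem(small_geometry, prof).adjoint(y)
        plain = WeightedSystem(small_geometry, None).adjoint(y)
        np.testing.assert_allclose(weighted, 0.6 * plain, atol=1e-10)


class TestRowNorm:
    def test_unit_weights_count_voxels(self, small_geometry):
        """Nearest-lattice rays at theta=0 cross exactly N unit coefficients."""
        prof = SensitivityProfile(s_min=1.0, s_max=1.0, extent=65)
        norms = row_norm(0, small_geometry, prof)
        assert norms[32] == pytest.approx(65.0, rel=1e-9)

    def test_central_ray_sums_squared_ramp(self, small_geometry, small_profile):
        norms = row_norm(0, small_geometry, small_profile)
        expected = np.sum(ramp_weight(np.arange(65), small_profile) ** 2)
        assert norms[32] == pytest.approx(expected, rel=1e-9)

    def test_quadratic_in_profile_scale(self, small_geometry):
        lo = SensitivityProfile(s_min=0.1, s_max=0.9, extent=65)
        hi = SensitivityProfile(s_min=0.3, s_max=2.7, extent=65)
        n_lo = row_norm(7, small_geometry, lo)
        n_hi = row_norm(7, small_geometry, hi)
        np.testing.assert_allclose(n_hi, 9.0 * n_lo, rtol=1e-9)

    def test_matches_dense_row_norms(self, small_profile):
        """Oracle: build the system matrix column by column and square rows."""
        g = GeometryConfig(n_angles=5, n_detector=12, image_shape=(9, 9))
        prof = SensitivityProfile(extent=9)
        system = WeightedSystem(g, prof)
        dense = np.zeros((5 * 12, 81))
        for j in range(81):
            e = np.zeros(81)
            e[j] = 1.0
            dense[:, j] = system.forward(e.reshape(9, 9)).ravel()
        expected = (dense**2).sum(axis=1).reshape(5, 12)
        np.testing.assert_allclose(system.row_norms, np.maximum(expected, 1e-12),
                                   rtol=1e-9, atol=1e-12)

    def test_invalid_angle_index(self, small_geometry, small_profile):
        with pytest.raises(ValueError):
            row_norm(45, small_geometry, small_profile)


@pytest.fixture(scope="module")
def clean(small_geometry):
    return unweighted_radon(_disk(65, 22.0), small_geometry)


class TestPoissonNoise:

    def test_seeded_determinism(self, clean):
        a = add_poisson_noise(clean, 10_000, seed=42)
        b = add_poisson_noise(clean, 10_000, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        c = add_poisson_noise(clean, 10_000, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_high_count_limit_recovers_input(self, clean):
        scale = np.abs(clean.values).max()
        err = [
            np.abs(add_poisson_noise(clean, n0, seed=1).values - clean.values).mean() / scale
            for n0 in (1_000, 100_000, 10_000_000)
        ]
        assert err[0] > err[1] > err[2]
        assert err[2] < 1e-3

    def test_noise_std_matches_delta_method(self, clean):
        """Monte-Carlo vs the first-order propagation 1/sqrt(N0 exp(-p))."""
        n0 = 10_000
        mu_ref = 4.0
        draws = np.stack([
            add_poisson_noise(clean, n0, seed=s).values for s in range(400)
        ])
        std = draws.std(axis=0)
        pmax = np.abs(clean.values).max()
        p_norm = clean.values / pmax * mu_ref
        predicted = 1.0 / np.sqrt(n0 * np.exp(-p_norm)) * pmax / mu_ref
        sel = clean.values > 0.2 * pmax  # bins with real signal
        ratio = std[sel] / predicted[sel]
        assert np.median(ratio) == pytest.approx(1.0, abs=0.1)

    def test_invalid_count_rejected(self, clean):
        with pytest.raises(ValueError):
            add_poisson_noise(clean, 0, seed=0)
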