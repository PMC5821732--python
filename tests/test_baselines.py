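"""Smoothing and regression baselines."""

import numpy as np
import pytest

from hicenhance import ContactMatrix
from hicenhance.baselines import (
    SmoothingConfig,
    anisotropic_diffusion,
    gaussian_smooth,
    mean_smooth,
    neighborhood_average_predict,
    rf_fit,
    rf_predict,
)

from .conftest import random_symmetric_counts


def _const(n, c=3.0):
    return ContactMatrix("c", 10_000, np.full((n, n), c))


class TestNeighborhoodAverage:
    def test_constant_matrix_unchanged(self):
        out = neighborhood_average_predict(_const(8), k=3)
        np.testing.assert_allclose(out.values, 3.0)

    def test_center_excluded(self):
        vals = np.zeros((3, 3))
        vals[1, 1] = 100.0
        out = neighborhood_average_predict(ContactMatrix("c", 10_000, vals), k=3)
        assert out.values[1, 1] == 0.0

    def test_matches_per_cell_loop_oracle(self, rng):
        m = random_symmetric_counts(rng, 10)
        out = neighborhood_average_predict(m, k=3)
        n = 10
        ref = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                block = m.values[max(0, i - 1) : i + 2, max(0, j - 1) : j + 2]
                ref[i, j] = (block.sum() - m.values[i, j]) / (block.size - 1)
        np.testing.assert_allclose(out.values, (ref + ref.T) / 2, atol=1e-12)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_average_predict(_const(5), k=4)


class TestKernelSmoothers:
    def test_gaussian_kernel_size_one_is_identity(self, small_counts):
        out = gaussian_smooth(small_counts, sigma=1.0, kernel_size=1)
        np.testing.assert_allclose(out.values, small_counts.values)

    def test_constant_unchanged(self):
        for fn in (lambda m: gaussian_smooth(m, 1.0, 5), lambda m: mean_smooth(m, 3)):
            np.testing.assert_allclose(fn(_const(9)).values, 3.0, atol=1e-12)

    def test_gaussian_matches_direct_convolution_oracle(self, rng):
        m = random_symmetric_counts(rng, 12)
        sigma, size = 1.0, 5
        half = size // 2
        ax = np.arange(-half, half + 1)
        kern = np.exp(-(np.add.outer(ax**2, ax**2)) / (2 * sigma**2))
        kern /= kern.sum()
        n = 12
        ref = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                acc = w = 0.0
                for u in range(-half, half + 1):
                    for v in range(-half, half + 1):
                        if 0 <= i + u < n and 0 <= j + v < n:
                            acc += kern[u + half, v + half] * m.values[i + u, j + v]
                            w += kern[u + half, v + half]
                ref[i, j] = acc / w
        out = gaussian_smooth(m, sigma, size)
        np.testing.assert_allclose(out.values, ref, atol=1e-8)

    def test_mean_smooth_hand_example(self):
        vals = np.ones((5, 5))
        vals[2, 2] = 10.0
        out = mean_smooth(ContactMatrix("c", 10_000, vals), kernel_size=3)
        assert out.values[2, 2] == pytest.approx((10 + 8) / 9)

    def test_mean_k1_identity(self, small_counts):
        np.testing.assert_allclose(mean_smooth(small_counts, 1).values, small_counts.values)

    def test_symmetry_preserved(self, rng):
        m = random_symmetric_counts(rng, 14)
        for out in (gaussian_smooth(m, 1.2, 5), mean_smooth(m, 3)):
            np.testing.assert_allclose(out.values, out.values.T, atol=1e-12)

    def test_linearity(self, rng):
        a = random_symmetric_counts(rng, 9)
        b = random_symmetric_counts(rng, 9)
        summed = ContactMatrix("c", 10_000, a.values + b.values)
        lhs = gaussian_smooth(summed, 1.0, 5).values
        rhs = gaussian_smooth(a, 1.0, 5).values + gaussian_smooth(b, 1.0, 5).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestDiffusion:
    def test_zero_iterations_identity(self, small_counts):
        out = anisotropic_diffusion(small_counts, n_iter=0)
        np.testing.assert_array_equal(out.values, small_counts.values)

    def test_constant_unchanged(self):
        out = anisotropic_diffusion(_const(7), n_iter=10)
        np.testing.assert_allclose(out.values, 3.0)

    def test_sum_conserved(self, rng):
        m = random_symmetric_counts(rng, 16)
        out = anisotropic_diffusion(m, n_iter=25, kappa=30.0, gamma=0.2)
        assert out.values.sum() == pytest.approx(m.values.sum(), rel=1e-8)

    def test_symmetry_preserved(self, rng):
        m = random_symmetric_counts(rng, 12)
        out = anisotropic_diffusion(m, n_iter=5)
        np.testing.assert_allclose(out.values, out.values.T, atol=1e-12)

    def test_unstable_gamma_rejected(self, small_counts):
        with pytest.raises(ValueError):
            anisotropic_diffusion(small_counts, gamma=0.3)


class TestSmoothingConfig:
    def test_dispatch(self, small_counts):
        for method in ("gaussian", "mean", "diffusion"):
            out = SmoothingConfig(method=method).apply(small_counts)
            assert out.n_bins == small_counts.n_bins

    def test_validation(self):
        with pytest.raises(ValueError):
            SmoothingConfig(method="box")
        with pytest.raises(ValueError):
            SmoothingConfig(kernel_size=4)
        with pytest.raises(ValueError):
            SmoothingConfig(gamma=0.5)


class TestRandomForest:
    def test_learns_identity_relation(self, rng):
        """Target equal to the window centre is learnable to R^2 > 0.95."""
        low = random_symmetric_counts(rng, 40, lam=10.0)
        handle = rf_fit(low, low, window=5, seed=0, n_estimators=30)
        rows, cols = handle._band_cells(40)
        X = handle._features(low.values, rows, cols)
        assert handle._forest.score(X, low.values[rows, cols]) > 0.95

    def test_deterministic_given_seed(self, rng):
        low = random_symmetric_counts(rng, 30, lam=2.0)
        high = random_symmetric_counts(rng, 30, lam=8.0)
        p1 = rf_predict(rf_fit(low, high, window=5, seed=3, n_estimators=20), low)
        p2 = rf_predict(rf_fit(low, high, window=5, seed=3, n_estimators=20), low)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_predictions_non_negative_and_symmetric(self, rng):
        low = random_symmetric_counts(rng, 30, lam=2.0)
        high = random_symmetric_counts(rng, 30, lam=8.0)
        pred = rf_predict(rf_fit(low, high, window=5, seed=0, n_estimators=20), low)
        assert np.all(pred.values >= 0)
        np.testing.assert_allclose(pred.values, pred.values.T)

    def test_band_restriction_keeps_input_outside(self, rng):
        low = random_symmetric_counts(rng, 30, lam=2.0)
        high = random_symmetric_counts(rng, 30, lam=8.0)
        handle = rf_fit(low, high, window=5, seed=0, n_estimators=10, max_dist_bins=5)
        pred = rf_predict(handle, low)
        assert pred.values[0, 20] == low.values[0, 20]

    def test_window_mismatch_errors(self, rng):
        low = random_symmetric_counts(rng, 30, lam=2.0)
        handle = rf_fit(low, low, window=5, seed=0, n_estimators=5)
        handle.window = 7
        with pytest.raises(ValueError):
            rf_predict(handle, low)
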