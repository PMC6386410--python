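"""Gaussian spatial-component forward model: covariance algebra, DAC shape."""

import numpy as np
import pytest

from ecogdac import (
    DACCurve,
    ModelMixingSpec,
    NoiseRefSpec,
    analytic_correlation,
    analytic_covariance,
    analytic_dac,
    build_distance_structure,
    fit_dac_gaussian,
    mean_model_dac,
    sample_mixing_matrix,
)
from ecogdac.forward_model import model_grid


class TestSampleMixingMatrix:
    def test_flat_limit_for_huge_sigma(self):
        spec = ModelMixingSpec(grid_shape=(4, 5), n_components=3,
                               sigma=1e6, center_margin_fraction=0.0, seed=0)
        mm = sample_mixing_matrix(spec)
        for c in range(3):
            col = mm.weights[:, c]
            assert np.ptp(col) / col.max() < 1e-6

    def test_weight_follows_gaussian_of_distance(self):
        spec = ModelMixingSpec(grid_shape=(1, 2), n_components=1, sigma=2.0,
                               amplitude_range=(1.0, 1.0),
                               amplitude_decay=0.0, seed=3)
        mm = sample_mixing_matrix(spec)
        grid = mm.grid
        d = np.linalg.norm(grid.positions - mm.centers[0], axis=1)
        np.testing.assert_allclose(mm.weights[:, 0],
                                   np.exp(-d**2 / (2 * 2.0**2)), rtol=1e-12)

    def test_seed_reproducibility(self):
        spec = ModelMixingSpec(seed=42)
        a = sample_mixing_matrix(spec).weights
        b = sample_mixing_matrix(spec).weights
        np.testing.assert_array_equal(a, b)

    def test_amplitudes_sorted_and_decayed(self):
        spec = ModelMixingSpec(n_components=10, amplitude_decay=0.1, seed=1)
        amps = sample_mixing_matrix(spec).amplitudes
        raw = amps * np.exp(0.1 * np.arange(1, 11))
        assert np.all(np.diff(raw) <= 0)
        assert np.all((raw >= 0.5) & (raw <= 1.5))


class TestAnalyticCovarianceCorrelation:
    def test_hand_examples(self):
        W = np.array([[1.0], [1.0]])
        np.testing.assert_allclose(analytic_covariance(W), [[1, 1], [1, 1]])
        np.testing.assert_allclose(
            analytic_covariance(W, NoiseRefSpec(epsilon=1.0)),
            [[2, 1], [1, 2]])
        empty = np.zeros((3, 0))
        np.testing.assert_allclose(
            analytic_covariance(empty, NoiseRefSpec(rho=2.0)),
            2.0 * np.ones((3, 3)))

    def test_correlation_from_covariance(self):
        W = np.array([[1.0], [1.0]])
        r = analytic_correlation(W, NoiseRefSpec(epsilon=1.0))
        assert r[0, 1] == pytest.approx(0.5)
        assert r[0, 0] == 1.0

    def test_rank_one_and_reference_dominance(self):
        W = np.array([[0.5], [1.5], [0.2]])
        np.testing.assert_allclose(analytic_correlation(W), 1.0, atol=1e-12)
        r = analytic_correlation(np.zeros((3, 1)) + 1e-3,
                                 NoiseRefSpec(epsilon=1e-6, rho=1e9))
        np.testing.assert_allclose(r, 1.0, atol=1e-6)

    def test_silent_channel_rejected(self):
        W = np.array([[1.0], [0.0]])
        with pytest.raises(ValueError, match="silent"):
            analytic_correlation(W)

    def test_correlation_invariant_to_column_rescaling(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0.1, 1.0, (6, 4))
        scales = rng.uniform(0.5, 2.0, 4)
        # scaling a weight column with its unit-variance component scaled
        # inversely leaves the data, hence covariance, unchanged only if both
        # move together; correlation of W itself changes.  The true ambiguity
        # is sign/permutation: correlation is invariant to column sign flips.
        flipped = W * np.where(scales > 1.0, -1.0, 1.0)
        np.testing.assert_allclose(analytic_correlation(W),
                                   analytic_correlation(flipped), atol=1e-12)


class TestAnalyticDAC:
    def test_dense_equal_components_match_sqrt2_gaussian(self):
        # many equal-amplitude components with generous margins: the
        # correlation approaches exp(-d^2 / (2 (sqrt(2) sigma)^2))
        sigma = 2.0
        spec = ModelMixingSpec(grid_shape=(10, 15), n_components=20000,
                               sigma=sigma, amplitude_range=(1.0, 1.0),
                               amplitude_decay=0.0,
                               center_margin_fraction=3.0, seed=7)
        mm = sample_mixing_matrix(spec)
        ds = build_distance_structure(mm.grid)
        curve = analytic_dac(mm, ds)
        sel = ds.unique_distances <= 3 * sigma
        expected = np.exp(-ds.unique_distances[sel]**2 / (4 * sigma**2))
        np.testing.assert_allclose(curve.mean[sel], expected, rtol=0.02)

    def test_noise_lowers_intercept_reference_raises_tail(self):
        spec = ModelMixingSpec(sigma=2.0, seed=11)
        mm = sample_mixing_matrix(spec)
        ds = build_distance_structure(mm.grid)
        base = analytic_dac(mm, ds).mean
        noisy = analytic_dac(mm, ds, NoiseRefSpec(epsilon=0.5)).mean
        refd = analytic_dac(mm, ds, NoiseRefSpec(rho=0.5)).mean
        assert noisy[0] < base[0]
        assert refd[-1] > base[-1]

    def test_dense_noiseless_dac_monotone_nonincreasing(self):
        spec = ModelMixingSpec(grid_shape=(10, 15), n_components=2000,
                               sigma=2.0, amplitude_range=(1.0, 1.0),
                               amplitude_decay=0.0, center_margin_fraction=2.0,
                               seed=5)
        mm = sample_mixing_matrix(spec)
        curve = analytic_dac(mm, grid=mm.grid)
        assert np.all(np.diff(curve.mean) <= 1e-3)

    def test_matches_sampled_recording_covariance(self, grid_7x8):
        # analytic covariance equals the sample covariance of a synthetic
        # recording built from the same weights, up to sampling error
        from ecogdac import SourceSpec, SyntheticRecordingSpec, generate_recording

        spec = SyntheticRecordingSpec(
            grid=grid_7x8,
            sources=[SourceSpec((0.8, 0.8), 0.6, 1.0, (20, 30)),
                     SourceSpec((2.0, 1.6), 0.6, 0.8, (20, 30))],
            noise_sd=0.1, sampling_rate=500.0, duration=120.0, seed=9,
        )
        rec, W = generate_recording(spec)
        target = analytic_covariance(W, NoiseRefSpec(epsilon=0.1**2))
        emp = np.cov(rec.data.T, bias=True)
        err = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert err < 0.15


class TestFitDacGaussian:
    def test_noiseless_recovery(self):
        d = np.linspace(0.5, 12, 30)
        s0 = 2.5
        y = np.exp(-d**2 / (2 * s0**2))
        curve = DACCurve(d, y, y, y, np.ones_like(d))
        fit = fit_dac_gaussian(curve)
        assert fit.sigma == pytest.approx(s0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_offset_and_amplitude_recovered(self):
        d = np.linspace(0.5, 12, 30)
        y = 0.6 * np.exp(-d**2 / (2 * 3.0**2)) + 0.25
        curve = DACCurve(d, y, y, y, np.ones_like(d))
        fit = fit_dac_gaussian(curve)
        assert fit.sigma == pytest.approx(3.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.6, abs=1e-6)
        assert fit.offset == pytest.approx(0.25, abs=1e-6)

    def test_flat_curve_degenerate(self):
        d = np.linspace(0.5, 12, 10)
        y = np.full_like(d, 0.4)
        fit = fit_dac_gaussian(DACCurve(d, y, y, y, np.ones_like(d)))
        assert fit.r_squared == pytest.approx(0.0, abs=1e-6)

    def test_too_few_distances_rejected(self):
        d = np.array([1.0, 2.0, 3.0])
        y = np.exp(-d)
        with pytest.raises(ValueError, match="4 distances"):
            fit_dac_gaussian(DACCurve(d, y, y, y, np.ones_like(d)))


class TestWidthLaw:
    def test_sqrt2_law_in_dense_equal_component_regime(self):
        # the model's own limit: many equal components, generous margins
        for sigma in (2.0, 3.0):
            spec = ModelMixingSpec(grid_shape=(10, 15), n_components=2000,
                                   sigma=sigma, amplitude_range=(1.0, 1.0),
                                   amplitude_decay=0.0,
                                   center_margin_fraction=3.0)
            curve, _ = mean_model_dac(sigma, n_iterations=20, spec=spec, seed=2)
            fit = fit_dac_gaussian(curve)
            assert fit.sigma / sigma == pytest.approx(np.sqrt(2), rel=0.03)
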