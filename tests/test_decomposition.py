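"""Whitening decomposition, reduced covariance/DAC attribution, CAR algebra."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from ecogdac import (
    apply_car,
    apply_car_to_weights,
    build_distance_structure,
    car_matrix,
    decompose_window,
    five_source_study_spec,
    generate_recording,
    reduced_covariance,
    reduced_dac,
)
from ecogdac.decomposition import MixingMatrix


def _matched_cosines(W_est, W_true):
    a = W_est / np.linalg.norm(W_est, axis=0)
    b = W_true / np.linalg.norm(W_true, axis=0)
    sim = np.abs(a.T @ b)
    ri, ci = linear_sum_assignment(-sim)
    return sim[ri, ci]


def _reduced_rank_cov(X, k):
    Xc = X - X.mean(0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    return (Vt[:k].T * (s[:k] ** 2 / X.shape[0])) @ Vt[:k]


class TestDecomposeWindow:
    @pytest.mark.parametrize("method", ["pca", "ica"])
    def test_whitening_identity_and_unit_variance(self, method):
        rec, _ = generate_recording(five_source_study_spec(seed=0, duration=6.0))
        mm = decompose_window(rec.data, method=method, n_keep=5, seed=0)
        covk = _reduced_rank_cov(rec.data, 5)
        err = np.linalg.norm(mm.covariance() - covk) / np.linalg.norm(covk)
        assert err < 1e-6
        z = mm.components
        np.testing.assert_allclose(z.var(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose((z @ z.T) / z.shape[1], np.eye(5), atol=1e-6)

    def test_ica_recovers_ground_truth_maps(self):
        rec, W_true = generate_recording(five_source_study_spec(seed=1))
        mm = decompose_window(rec.data, method="ica", n_keep=5, seed=0)
        cos = _matched_cosines(mm.weights, W_true)
        assert cos.min() > 0.95

    def test_pca_on_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5000, 8))
        mm = decompose_window(X, method="pca", n_keep=8)
        var = (mm.weights**2).sum(axis=0)
        share = var / var.sum()
        assert np.all(share > 0.5 / 8) and np.all(share < 2.0 / 8)

    def test_components_ordered_and_sign_canonical(self):
        rec, _ = generate_recording(five_source_study_spec(seed=3, duration=6.0))
        mm = decompose_window(rec.data, method="ica", n_keep=5, seed=0)
        power = (mm.weights**2).sum(axis=0)
        assert np.all(np.diff(power) <= 1e-12)
        peaks = np.abs(mm.weights).argmax(axis=0)
        assert np.all(mm.weights[peaks, np.arange(5)] > 0)

    def test_default_n_keep_respects_cap_and_variance(self):
        rec, _ = generate_recording(five_source_study_spec(seed=4, duration=6.0))
        mm = decompose_window(rec.data, method="pca", seed=0)
        assert mm.n_components <= 30
        covk = _reduced_rank_cov(rec.data, mm.n_components)
        full = np.cov(rec.data.T, bias=True)
        assert np.trace(covk) / np.trace(full) >= 0.95

    def test_short_window_warns(self):
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning, match="samples"):
            decompose_window(rng.standard_normal((10, 20)), method="pca")


class TestReducedCovariance:
    def test_hand_outer_products(self):
        W = np.array([[1.0, 1.0], [1.0, -1.0]])
        np.testing.assert_allclose(reduced_covariance(W, 0), [[1, 1], [1, 1]])
        np.testing.assert_allclose(reduced_covariance(W, 1), [[1, -1], [-1, 1]])
        total = reduced_covariance(W, 0) + reduced_covariance(W, 1)
        np.testing.assert_allclose(total, [[2, 0], [0, 2]])

    def test_single_component_equals_full(self):
        W = np.array([[0.3], [1.2], [0.7]])
        np.testing.assert_allclose(reduced_covariance(W, 0), W @ W.T)

    def test_bad_index_rejected(self):
        with pytest.raises(IndexError):
            reduced_covariance(np.ones((3, 2)), 2)


class TestReducedDAC:
    def test_hand_example_two_channel(self):
        # W = [[1,1],[1,-1]]: full r12 = 0, component shares +0.5 / -0.5
        from ecogdac import ElectrodeGrid

        g = ElectrodeGrid.rectangular(1, 2, 1.0)
        ds = build_distance_structure(g)
        W = np.array([[1.0, 1.0], [1.0, -1.0]])
        contrib = reduced_dac(W, ds)
        np.testing.assert_allclose(contrib.reduced_curves[:, 0], [0.5, -0.5])
        np.testing.assert_allclose(contrib.full_curve, [0.0], atol=1e-12)
        np.testing.assert_allclose(contrib.percent_variance, [50.0, 50.0])
        # total drop is 0 - 1 = -1; component 1 drops 0, component 2 drops -1
        np.testing.assert_allclose(contrib.percent_dac_drop, [0.0, 100.0],
                                   atol=1e-12)

    def test_component_curves_sum_to_full(self, ds_7x8):
        rec, _ = generate_recording(five_source_study_spec(seed=6, duration=6.0))
        mm = decompose_window(rec.data, method="ica", n_keep=6, seed=0)
        contrib = reduced_dac(mm, ds_7x8)
        np.testing.assert_allclose(contrib.reduced_curves.sum(axis=0),
                                   contrib.full_curve, atol=1e-9)
        np.testing.assert_allclose(contrib.reduced_drops.sum(axis=0),
                                   contrib.full_drop, atol=1e-9)
        assert contrib.percent_variance.sum() == pytest.approx(100.0, abs=0.1)

    def test_flat_component_carries_variance_but_no_drop(self, ds_7x8):
        W = np.ones((56, 1))
        with pytest.warns(UserWarning, match="near-zero total"):
            contrib = reduced_dac(W, ds_7x8)
        assert contrib.percent_variance[0] == pytest.approx(100.0)
        assert np.isnan(contrib.percent_dac_drop[0])

    def test_pca_top_quartile_more_gaussian_than_bottom(self, grid_7x8, ds_7x8):
        # spatially coherent sources concentrate in the leading PCs: the
        # variance-weighted spatial-fit R² of the top quartile exceeds the
        # bottom quartile's
        from ecogdac import fit_component_map

        rec, _ = generate_recording(
            five_source_study_spec(seed=7, noise_sd=0.2))
        mm = decompose_window(rec.data, method="pca", n_keep=16, seed=0)
        r2 = np.array([fit_component_map(mm.weights[:, c], grid_7x8).r_squared
                       for c in range(mm.n_components)])
        var = (mm.weights**2).sum(axis=0)
        q = mm.n_components // 4
        top = np.average(r2[:q], weights=var[:q])
        bottom = np.average(r2[-q:], weights=var[-q:])
        assert top > bottom


class TestCommonAverageReference:
    def test_car_matrix_properties(self):
        C = car_matrix(2)
        np.testing.assert_allclose(C, [[0.5, -0.5], [-0.5, 0.5]])
        C5 = car_matrix(5)
        np.testing.assert_allclose(C5 @ C5, C5, atol=1e-12)
        np.testing.assert_allclose(C5 @ np.ones(5), 0.0, atol=1e-12)
        np.testing.assert_allclose(C5.sum(axis=1), 0.0, atol=1e-12)
        with pytest.raises(ValueError):
            car_matrix(1)

    def test_weights_recentred_and_reference_annihilated(self):
        W = np.column_stack([np.full(4, 2.5), [1.0, 0.0, 0.0, 0.0]])
        mm = MixingMatrix(W, np.zeros((2, 10)))
        out = apply_car_to_weights(mm)
        np.testing.assert_allclose(out.weights[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.weights[:, 1],
                                   [0.75, -0.25, -0.25, -0.25])
        np.testing.assert_allclose(out.weights.mean(axis=0), 0.0, atol=1e-12)
        # equals C @ W
        np.testing.assert_allclose(out.weights, car_matrix(4) @ W, atol=1e-12)

    def test_car_covariance_identity(self):
        rec, _ = generate_recording(five_source_study_spec(seed=8, duration=4.0))
        X = rec.data
        C = car_matrix(X.shape[1])
        cov = np.cov(X.T, bias=True)
        cov_car = np.cov(apply_car(X).T, bias=True)
        np.testing.assert_allclose(cov_car, C @ cov @ C.T, atol=1e-9)
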