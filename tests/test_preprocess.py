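"""Preprocessing operators: definitional examples, independent oracles,
shape/row-locality invariants, and fit-on-train leakage safety."""

import numpy as np
import pytest

from meatspec.preprocess import (PAPER_PREPROCESSORS, FittedTransform,
                                 PreprocessError, PreprocessSpec,
                                 apply_pipeline, atr_correct, deresolve,
                                 detrend, median_filter5, msc_fit_apply,
                                 osc_fit, osc_fit_apply, quantile_normalize,
                                 sg_derivative, snv, snv_detrend)

from conftest import make_set

ALL_NAMES = list(PAPER_PREPROCESSORS) + ["atr_correct"]


class TestSavitzkyGolay:
    def test_constant_spectrum_derivative_zero(self):
        s = make_set(np.full((3, 50), 1.7))
        out = sg_derivative(s, order=1, window=5, polyorder=2)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_exact_on_quadratic(self):
        # f(nu) = nu^2 -> f'(nu) = 2 nu, exact for SG with polyorder >= 2
        w = np.arange(100.0, 160.0)  # unit spacing
        s = make_set((w**2)[None, :], wavenumbers=w)
        out = sg_derivative(s, order=1, window=5, polyorder=2)
        np.testing.assert_allclose(out.absorbance[0, 2:-2], 2 * w[2:-2], rtol=1e-9)

    def test_matches_local_least_squares_oracle(self, rng):
        # brute force: fit a polynomial in each window by normal equations,
        # read the derivative at the centre
        w = 600.0 + 2.0 * np.arange(41)
        y = rng.normal(size=41)
        s = make_set(y[None, :], wavenumbers=w)
        window, poly = 7, 3
        out = sg_derivative(s, order=1, window=window, polyorder=poly)
        half = window // 2
        for c in range(half, 41 - half):
            t = (w[c - half:c + half + 1] - w[c])
            basis = np.vander(t, poly + 1, increasing=True)
            coef, *_ = np.linalg.lstsq(basis, y[c - half:c + half + 1], rcond=None)
            assert out.absorbance[0, c] == pytest.approx(coef[1], rel=1e-8, abs=1e-10)

    def test_segmented_axis_matches_per_segment_filters(self, rng):
        # a gap in the axis: filtering the full set equals filtering each
        # contiguous block separately
        w = np.concatenate([600 + 2.0 * np.arange(30), 800 + 2.0 * np.arange(30)])
        x = rng.normal(size=(2, 60))
        s = make_set(x, wavenumbers=w)
        out = sg_derivative(s, order=1, window=7, polyorder=2)
        left = sg_derivative(make_set(x[:, :30], wavenumbers=w[:30]), 1, 7, 2)
        right = sg_derivative(make_set(x[:, 30:], wavenumbers=w[30:]), 1, 7, 2)
        np.testing.assert_allclose(out.absorbance[:, :30], left.absorbance)
        np.testing.assert_allclose(out.absorbance[:, 30:], right.absorbance)

    def test_irregular_grid_rejected(self, rng):
        w = np.sort(rng.uniform(600, 700, size=30))
        s = make_set(np.zeros((1, 30)), wavenumbers=w)
        with pytest.raises(PreprocessError, match="not uniform"):
            sg_derivative(s, order=1, window=5, polyorder=2)


class TestSNV:
    def test_three_point_row(self):
        out = snv(make_set(np.array([[1.0, 2.0, 3.0]])))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        s = make_set(rng.normal(size=(5, 40)))
        once = snv(s)
        twice = snv(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)

    def test_row_statistics(self, rng):
        out = snv(make_set(rng.normal(2.0, 3.0, size=(50, 80))))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0,
                                   atol=1e-12)

    def test_constant_row_named(self):
        s = make_set(np.vstack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(PreprocessError, match="row 0"):
            snv(s)


class TestMSC:
    def test_reference_row_unchanged(self, rng):
        base = rng.normal(size=20)
        s = make_set(np.tile(base, (4, 1)))
        out = msc_fit_apply(s, s)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-10)

    def test_affine_distortion_recovered(self, rng):
        ref = np.sin(np.linspace(0, 3, 50)) + 2
        train = make_set(np.tile(ref, (3, 1)))
        distorted = make_set((3.0 + 2.0 * ref)[None, :])
        out = msc_fit_apply(train, distorted)
        np.testing.assert_allclose(out.absorbance[0], ref, rtol=1e-9)

    def test_slope_intercept_match_normal_equations(self, rng):
        train = make_set(rng.normal(size=(6, 30)) + np.linspace(1, 2, 30))
        row = rng.normal(size=30) + 5
        ref = train.absorbance.mean(axis=0)
        design = np.column_stack([np.ones(30), ref])
        a, b = np.linalg.solve(design.T @ design, design.T @ row)
        out = msc_fit_apply(train, make_set(row[None, :]))
        np.testing.assert_allclose(out.absorbance[0], (row - a) / b, rtol=1e-9)


class TestDetrend:
    def test_linear_baseline_removed(self):
        w = 600.0 + 2.0 * np.arange(80)
        s = make_set((5 + 0.01 * w)[None, :], wavenumbers=w)
        out = detrend(s, degree=1)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)

    def test_degree_zero_is_mean_centering(self, rng):
        s = make_set(rng.normal(size=(4, 30)))
        out = detrend(s, degree=0)
        expected = s.absorbance - s.absorbance.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out.absorbance, expected, atol=1e-10)

    def test_matches_polynomial_regression_oracle(self, rng):
        w = 600.0 + 2.0 * np.arange(60)
        row = 0.5 + 1e-3 * w + 1e-6 * w**2 + np.exp(-((w - 660) / 8) ** 2)
        s = make_set(row[None, :], wavenumbers=w)
        out = detrend(s, degree=2)
        basis = np.vander((w - w.mean()) / np.ptp(w), 3, increasing=True)
        coef, *_ = np.linalg.lstsq(basis, row, rcond=None)
        np.testing.assert_allclose(out.absorbance[0], row - basis @ coef,
                                   atol=1e-9)

    def test_degree_too_large(self):
        with pytest.raises(PreprocessError):
            detrend(make_set(np.zeros((1, 4))), degree=4)


class TestMedianFilter:
    def test_spike_removed(self):
        out = median_filter5(make_set(np.array([[1.0, 1, 9, 1, 1]])), width=5)
        assert out.absorbance[0, 2] == 1.0

    def test_monotone_interior_unchanged(self):
        row = np.arange(20.0)
        out = median_filter5(make_set(row[None, :]), width=5)
        np.testing.assert_allclose(out.absorbance[0, 2:-2], row[2:-2])

    def test_matches_naive_oracle_including_edges(self, rng):
        row = rng.normal(size=31)
        width = 5
        out = median_filter5(make_set(row[None, :]), width=width)
        half = width // 2
        padded = np.concatenate([row[half - 1::-1], row, row[:-half - 1:-1]])
        oracle = [np.median(np.sort(padded[i:i + width]))
                  for i in range(31)]
        np.testing.assert_allclose(out.absorbance[0], oracle)

    def test_even_width_rejected(self):
        with pytest.raises(PreprocessError, match="odd"):
            median_filter5(make_set(np.zeros((1, 10))), width=4)


class TestQuantile:
    def test_two_rows_rank_mean(self):
        train = make_set(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        out = quantile_normalize(train, train)
        np.testing.assert_allclose(out.absorbance,
                                   [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_identical_rows_unchanged(self):
        row = np.array([0.3, 0.1, 0.7, 0.5])
        train = make_set(np.tile(row, (3, 1)))
        out = quantile_normalize(train, train)
        np.testing.assert_allclose(out.absorbance, train.absorbance)

    def test_all_rows_share_sorted_values(self, rng):
        train = make_set(rng.normal(size=(20, 40)))
        out = quantile_normalize(train, train)
        sorted_rows = np.sort(out.absorbance, axis=1)
        np.testing.assert_allclose(sorted_rows,
                                   np.tile(sorted_rows[0], (20, 1)))

    def test_ties_get_average_reference(self):
        train = make_set(np.array([[0.0, 1.0, 2.0, 3.0], [0, 1, 2, 3.0]]))
        tied = make_set(np.array([[5.0, 5.0, 1.0, 9.0]]))
        out = quantile_normalize(train, tied)
        # ranks: the two 5.0s tie at ranks 2-3 -> mean of ref[1], ref[2]
        np.testing.assert_allclose(out.absorbance[0], [1.5, 1.5, 0.0, 3.0])


class TestOSC:
    def test_scores_orthogonal_to_response(self, rng):
        x = rng.normal(size=(40, 60))
        y = rng.integers(0, 2, size=40).astype(float)
        s = make_set(x, labels=y.astype(int))
        x_mean, w, p, scores, k = osc_fit(s, y, n_components=2)
        assert k == 2
        for a in range(k):
            t = scores[:, a]
            assert abs(t @ y) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(y)

    def test_planted_artifact_removed_signal_kept(self, rng):
        n, p_dim = 120, 80
        y = np.tile([0.0, 1.0], n // 2)
        signal_dir = np.zeros(p_dim); signal_dir[10] = 1.0
        artifact_dir = np.zeros(p_dim); artifact_dir[50] = 1.0
        artifact_amp = rng.normal(0, 5.0, size=n)
        x = (np.outer(y - y.mean(), signal_dir) * 3.0
             + np.outer(artifact_amp, artifact_dir)
             + rng.normal(0, 0.01, size=(n, p_dim)))
        s = make_set(x, labels=y.astype(int))
        out = osc_fit_apply(s, y, 1, s)
        var_before = np.var(x[:, 50])
        var_after = np.var(out.absorbance[:, 50])
        assert var_after <= 0.05 * var_before
        sig_before = np.var(x[:, 10])
        sig_after = np.var(out.absorbance[:, 10])
        assert sig_after >= 0.95 * sig_before

    def test_zero_components_identity(self, rng):
        s = make_set(rng.normal(size=(10, 15)))
        out = osc_fit_apply(s, s.label.astype(float), 0, s)
        np.testing.assert_array_equal(out.absorbance, s.absorbance)


class TestDeresolveAtrCombined:
    def test_deresolve_constant_zero(self):
        out = deresolve(make_set(np.full((2, 40), 3.0)))
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_deresolve_equals_smooth_then_derivative(self, rng):
        s = make_set(rng.normal(size=(3, 50)))
        via_compose = sg_derivative(sg_derivative(s, 0, 11, 2), 1, 11, 2)
        np.testing.assert_allclose(deresolve(s, 11, 2).absorbance,
                                   via_compose.absorbance)

    def test_deresolve_beats_raw_difference_on_noisy_ramp(self, rng):
        w = 600.0 + 2.0 * np.arange(200)
        slope = 0.01
        errs_deres, errs_diff = [], []
        for seed in range(10):
            r = np.random.default_rng(seed)
            row = slope * w + r.normal(0, 0.05, size=200)
            s = make_set(row[None, :], wavenumbers=w)
            d = deresolve(s, 11, 2).absorbance[0, 20:-20]
            raw_diff = np.diff(row) / 2.0
            errs_deres.append(np.mean((d - slope) ** 2))
            errs_diff.append(np.mean((raw_diff[20:-20] - slope) ** 2))
        assert np.mean(errs_deres) < np.mean(errs_diff)

    def test_atr_reference_column_fixed_and_linear(self):
        w = np.array([500.0, 1000.0, 2000.0])
        s = make_set(np.ones((1, 3)), wavenumbers=w)
        out = atr_correct(s, reference_wavenumber=1000.0)
        np.testing.assert_allclose(out.absorbance[0], [0.5, 1.0, 2.0])

    def test_atr_roundtrip(self, rng):
        s = make_set(rng.normal(size=(3, 30)))
        out = atr_correct(s, 620.0)
        back = out.with_absorbance(out.absorbance / (s.wavenumbers / 620.0))
        np.testing.assert_allclose(back.absorbance, s.absorbance, rtol=1e-12)

    def test_snv_detrend_equals_composition(self, rng):
        s = make_set(rng.normal(size=(6, 40)))
        np.testing.assert_allclose(snv_detrend(s, 2).absorbance,
                                   detrend(snv(s), 2).absorbance)

    def test_snv_detrend_kills_polynomials(self, rng):
        s = make_set(rng.normal(size=(4, 50)))
        out = snv_detrend(s, degree=2)
        w = s.wavenumbers
        basis = np.vander((w - w.mean()) / np.ptp(w), 3, increasing=True)
        q, _ = np.linalg.qr(basis)
        proj = out.absorbance @ q
        np.testing.assert_allclose(proj, 0.0, atol=1e-9)


class TestPipeline:
    @pytest.mark.parametrize("name", ALL_NAMES)
    def test_shape_preserved(self, name, small_dataset):
        from meatspec.io import average_replicates
        data = average_replicates(small_dataset)
        tr, te, _ = apply_pipeline([name], data, data)
        assert tr.absorbance.shape == data.absorbance.shape
        assert te.absorbance.shape == data.absorbance.shape

    @pytest.mark.parametrize("name", ["snv", "detrend", "sg1", "median5",
                                      "atr_correct"])
    def test_stateless_transforms_are_row_local(self, name, rng):
        s = make_set(rng.normal(size=(8, 64)),
                     wavenumbers=900.0 + 2.0 * np.arange(64))
        perm = rng.permutation(8)
        direct, _, _ = apply_pipeline([name], s)
        permuted, _, _ = apply_pipeline([name], s.rows(perm))
        np.testing.assert_allclose(permuted.absorbance,
                                   direct.absorbance[perm], atol=1e-12)

    def test_raw_is_identity(self, rng):
        s = make_set(rng.normal(size=(5, 20)))
        tr, te, _ = apply_pipeline(["raw"], s, s)
        np.testing.assert_array_equal(tr.absorbance, s.absorbance)
        np.testing.assert_array_equal(te.absorbance, s.absorbance)

    def test_chain_equals_manual_composition(self, rng):
        s = make_set(rng.normal(size=(6, 30)))
        tr, _, _ = apply_pipeline(["snv", "detrend"], s)
        np.testing.assert_allclose(tr.absorbance,
                                   detrend(snv(s), 1).absorbance, atol=1e-12)

    def test_fitted_state_invariant_to_training_order(self, rng):
        s = make_set(rng.normal(size=(12, 25)))
        perm = rng.permutation(12)
        probe = make_set(rng.normal(size=(3, 25)))
        for name in ("msc", "quantile", "osc"):
            _, out_a, _ = apply_pipeline([name], s, probe)
            _, out_b, _ = apply_pipeline([name], s.rows(perm), probe)
            np.testing.assert_allclose(out_a.absorbance, out_b.absorbance,
                                       atol=1e-8)

    def test_osc_without_labels_impossible_by_construction(self, rng):
        # OSC pulls labels from the training SpectraSet; a deliberately
        # unlabeled call path must raise
        s = make_set(rng.normal(size=(6, 10)))
        with pytest.raises(PreprocessError, match="labels"):
            from meatspec.preprocess import _fit_one
            _fit_one(PreprocessSpec("osc"), s, None)

    def test_unknown_transform_rejected(self):
        with pytest.raises(PreprocessError, match="unknown"):
            PreprocessSpec("wavelet")

    def test_invalid_params_rejected(self):
        with pytest.raises(PreprocessError):
            PreprocessSpec("sg1", {"window": 8})
        with pytest.raises(PreprocessError):
            PreprocessSpec("median5", {"width": 4})
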