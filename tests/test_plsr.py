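"""PLS1 regression, LV selection, VIP scores, RMSE and the 0.5-threshold rule."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from meatspec.metrics import rmse
from meatspec.plsr import (fit_plsr, nipals_pls1, predict,
                           predict_and_classify, vip_scores, _beta_from)

from conftest import make_set


def _fit_direct(x, y, a):
    """Full-data fit at a fixed LV count, bypassing LOO selection."""
    w, p, q, s_a, xm, ym, got = nipals_pls1(x, y, a)
    beta = _beta_from(w, p, q, got)
    return w, p, q, s_a, xm, ym, beta


class TestFit:
    def test_exact_linear_single_column_predictor(self, rng):
        # noiseless y linear in one column; columns sample-orthogonal so the
        # first weight vector points exactly along that column
        n = 25
        x = rng.normal(size=(n, 6))
        x -= x.mean(axis=0)
        x, _ = np.linalg.qr(x, mode="reduced")[0], None
        x = x[:, :6]
        y = 2.0 + 3.0 * x[:, 2]
        *_, beta = _fit_direct(x, y, 1)
        yhat = y.mean() + (x - x.mean(0)) @ beta
        assert rmse(y, yhat) <= 1e-8

    def test_beta_matches_independent_pls1_implementation(self, rng):
        # sklearn's PLSRegression is an independent NIPALS implementation
        for _ in range(5):
            x = rng.normal(size=(20, 6))
            y = rng.normal(size=20)
            for a in (1, 2, 4):
                *_, beta = _fit_direct(x, y, a)
                sk = PLSRegression(n_components=a, scale=False).fit(x, y)
                np.testing.assert_allclose(beta, sk.coef_.ravel(), rtol=1e-8,
                                           atol=1e-10)

    def test_row_permutation_leaves_beta_unchanged(self, rng):
        x = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        perm = rng.permutation(30)
        *_, b1 = _fit_direct(x, y, 3)
        *_, b2 = _fit_direct(x[perm], y[perm], 3)
        np.testing.assert_allclose(b1, b2, atol=1e-10)

    def test_training_rmse_non_increasing_in_lv(self, rng):
        x = rng.normal(size=(25, 15))
        y = rng.normal(size=25)
        prev = np.inf
        for a in range(1, 10):
            *_, beta = _fit_direct(x, y, a)
            err = rmse(y, y.mean() + (x - x.mean(0)) @ beta)
            assert err <= prev + 1e-10
            prev = err

    def test_loo_selection_reports_minimum(self, small_dataset):
        from meatspec.io import average_replicates
        data = average_replicates(small_dataset)
        model, sel = fit_plsr(data, max_lv=8)
        assert sel.chosen == sel.candidates[np.argmin(sel.rmse_loo)]


class TestVip:
    def test_equal_weights_single_lv_gives_unit_vip(self):
        # one LV, all weights equal magnitude -> every VIP forced to 1
        rngl = np.random.default_rng(0)
        n, p = 30, 8
        t = rngl.normal(size=n)
        x = np.outer(t, np.ones(p)) + rngl.normal(0, 1e-8, size=(n, p))
        y = t.copy()
        w, pl, q, s_a, xm, ym, _ = nipals_pls1(x, y, 1)
        model = _model_from(w, pl, q, s_a, xm, ym)
        np.testing.assert_allclose(vip_scores(model), 1.0, atol=1e-4)

    def test_mean_squared_vip_is_one(self, rng):
        for _ in range(5):
            x = rng.normal(size=(20, 12))
            y = rng.normal(size=20)
            w, pl, q, s_a, xm, ym, _ = nipals_pls1(x, y, 4)
            v = vip_scores(_model_from(w, pl, q, s_a, xm, ym))
            assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)

    def test_planted_band_out_vips_noise(self):
        wins = 0
        for seed in range(20):
            rngl = np.random.default_rng(seed)
            n, p = 80, 50
            y = np.tile([0.0, 1.0], n // 2)
            x = rngl.normal(size=(n, p))
            x[:, 7] = (y - 0.5) * 5.0 + rngl.normal(0, 1.0, size=n)  # SNR 5
            w, pl, q, s_a, xm, ym, _ = nipals_pls1(x, y, 3)
            v = vip_scores(_model_from(w, pl, q, s_a, xm, ym))
            noise_vips = np.delete(v, 7)
            wins += v[7] > np.percentile(noise_vips, 95)
        assert wins >= 18


class TestPredictClassify:
    def test_half_is_class_zero(self, rng):
        s = make_set(rng.normal(size=(20, 5)),
                     labels=np.tile([0, 1], 10))
        model, _ = fit_plsr(s, max_lv=3)
        model.beta = np.zeros(5)
        model.y_mean = 0.5
        yhat, labels = predict_and_classify(model, s)
        np.testing.assert_allclose(yhat, 0.5)
        assert np.all(labels == 0)  # strict > 0.5

    def test_separated_training_data_recovered(self):
        rngl = np.random.default_rng(1)
        n = 30
        y = np.tile([0, 1], n // 2)
        x = rngl.normal(size=(n, 10))
        x[:, 0] += (y - 0.5) * 10
        s = make_set(x, labels=y)
        model, _ = fit_plsr(s, max_lv=5)
        _, labels = predict_and_classify(model, s)
        np.testing.assert_array_equal(labels, y)

    def test_axis_mismatch_rejected(self, rng):
        s = make_set(rng.normal(size=(15, 8)), labels=np.tile([0, 1], [8])[:15])
        model, _ = fit_plsr(s, max_lv=2)
        other = make_set(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError, match="axis"):
            predict(model, other)


class TestRmse:
    def test_exact_predictions(self):
        assert rmse([0, 1], [0, 1]) == 0.0

    def test_constant_half(self):
        assert rmse([0, 1], [0.5, 0.5]) == pytest.approx(0.5)

    def test_matches_brute_force_loop(self, rng):
        y = rng.normal(size=40)
        yhat = rng.normal(size=40)
        oracle = np.sqrt(sum((a - b) ** 2 for a, b in zip(y, yhat)) / 40)
        assert rmse(y, yhat) == pytest.approx(oracle, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestGeneralization:
    def test_loo_rmse_exceeds_training_rmse_on_average(self):
        gaps = []
        for seed in range(20):
            rngl = np.random.default_rng(seed)
            n, p = 30, 40
            y = np.tile([0, 1], n // 2)
            x = rngl.normal(size=(n, p))
            x[:, :3] += np.outer(y - 0.5, [2.0, 1.5, 1.0])
            s = make_set(x, labels=y)
            model, sel = fit_plsr(s, max_lv=8)
            train_err = rmse(y, predict(model, s))
            loo_err = float(sel.rmse_loo[np.argmin(np.abs(
                sel.candidates - model.n_components))])
            gaps.append(loo_err - train_err)
        assert np.mean(gaps) >= 0

    def test_parameter_recovery_at_snr_10(self):
        cors = []
        for seed in range(20):
            rngl = np.random.default_rng(seed)
            n, p = 100, 50
            beta_true = np.zeros(p)
            beta_true[[5, 20, 35]] = [1.0, -0.8, 0.6]
            x = rngl.normal(size=(n, p))
            signal = x @ beta_true
            noise_sd = signal.std() / np.sqrt(10.0)
            y = signal + rngl.normal(0, noise_sd, size=n)
            w, pl, q, s_a, xm, ym, _ = nipals_pls1(x, y, 10)
            beta = _beta_from(w, pl, q, 6)
            cors.append(np.corrcoef(beta, beta_true)[0, 1])
        assert np.mean(cors) >= 0.8


def _model_from(w, pl, q, s_a, xm, ym):
    from meatspec.plsr import PLSRModel, _beta_from

    a = w.shape[1]
    return PLSRModel(
        weights=w, x_loadings=pl, y_loadings=q,
        beta=_beta_from(w, pl, q, a), x_mean=xm, y_mean=ym,
        n_components=a, s_a=s_a, vip=np.empty(0),
        wavenumbers=600 + 2.0 * np.arange(w.shape[0]),
    )
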