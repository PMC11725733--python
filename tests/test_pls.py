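import numpy as np
import pandas as pd
import pytest

import porkfresh as pf
from porkfresh.errors import DomainError
from porkfresh.pls import MetricSet


class TestFitPredict:
    def test_exact_linear_map_interpolated(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0] + 7.0
        fit = pf.fit_plsr(X, y, 4)
        assert pf.rmse(y, fit.fitted_values[:, 0]) < 1e-8

    def test_single_informative_column(self, rng):
        # x1 carries y exactly; remaining columns are orthogonal to y
        # (all columns pre-centered so NIPALS centering is a no-op)
        n = 64
        x1 = rng.normal(size=n)
        x1 -= x1.mean()
        Q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        Q -= Q.mean(axis=0)
        resid = Q - x1[:, None] * (x1 @ Q) / (x1 @ x1)
        X = np.column_stack([x1, resid])
        y = 2.0 * x1
        fit = pf.fit_plsr(X, y, 1)
        assert fit.coefficients[0, 0] == pytest.approx(2.0, abs=1e-6)
        np.testing.assert_allclose(fit.coefficients[1:, 0], 0.0, atol=1e-6)

    def test_one_column_equals_simple_regression(self, rng):
        x = rng.normal(size=(25, 1))
        y = 3.0 * x[:, 0] + rng.normal(size=25)
        fit = pf.fit_plsr(x, y, 1)
        slope = np.polyfit(x[:, 0], y, 1)[0]
        assert fit.coefficients[0, 0] == pytest.approx(slope, abs=1e-10)

    def test_full_rank_matches_ols(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=40) * 0.3
        fit = pf.fit_plsr(X, y, 6)
        A = np.column_stack([np.ones(40), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        ols_pred = A @ beta
        np.testing.assert_allclose(
            pf.predict_plsr(fit, X), ols_pred, atol=1e-8
        )

    def test_matches_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(50, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=50)
        ours = pf.fit_plsr(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(
            ours.coefficients[:, 0], ref.coef_.ravel(), atol=1e-8
        )

    def test_predict_reproduces_fitted_values(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        fit = pf.fit_plsr(X, y, 3)
        np.testing.assert_allclose(
            pf.predict_plsr(fit, X), fit.fitted_values[:, 0], atol=1e-12
        )

    def test_predict_row_order_invariant(self, rng):
        X = rng.normal(size=(20, 5))
        fit = pf.fit_plsr(X, rng.normal(size=20), 2)
        Xn = rng.normal(size=(7, 5))
        perm = rng.permutation(7)
        np.testing.assert_allclose(
            pf.predict_plsr(fit, Xn)[perm], pf.predict_plsr(fit, Xn[perm])
        )

    def test_column_mismatch_raises(self, rng):
        fit = pf.fit_plsr(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        with pytest.raises(DomainError):
            pf.predict_plsr(fit, rng.normal(size=(3, 5)))

    def test_autoscale_zero_variance_column_listed(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 5.0
        with pytest.raises(DomainError, match="b"):
            pf.fit_plsr(
                X, rng.normal(size=10), 2, scaling="autoscale",
                variable_names=["a", "b", "c"],
            )

    def test_n_lv_bounds_enforced(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(DomainError):
            pf.fit_plsr(X, rng.normal(size=10), 10)


class TestVenetianBlinds:
    def test_interleaved_assignment(self):
        folds = pf.venetian_blinds_folds(20, 10)
        for k in range(10):
            np.testing.assert_array_equal(
                np.flatnonzero(folds == k), [k, k + 10]
            )

    def test_loo_when_n_equals_splits(self):
        folds = pf.venetian_blinds_folds(10, 10)
        assert sorted(folds) == list(range(10))

    def test_partition_exact(self):
        folds = pf.venetian_blinds_folds(47, 10)
        assert folds.size == 47
        assert set(folds) == set(range(10))

    def test_errors(self):
        with pytest.raises(DomainError):
            pf.venetian_blinds_folds(5, 1)
        with pytest.raises(DomainError):
            pf.venetian_blinds_folds(5, 10)


class TestSelectLvs:
    def test_rank_two_signal_found(self, rng):
        basis = rng.normal(size=(2, 12))
        scores = rng.normal(size=(80, 2))
        X = scores @ basis + rng.normal(size=(80, 12)) * 1e-8
        y = scores @ [1.5, -2.0]
        n_lv, curve = pf.select_lvs(X, y, 6)
        assert n_lv == 2
        assert curve[1] < 1e-6

    def test_pure_noise_prefers_few_lvs(self, rng):
        X = rng.normal(size=(60, 10))
        y = rng.normal(size=60)
        n_lv, _ = pf.select_lvs(X, y, 8)
        assert n_lv <= 4

    def test_capped_with_warning(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="capped"):
            n_lv, curve = pf.select_lvs(X, y, 10)
        assert curve.size == 3


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        m = pf.compute_metrics(cal=(y, y), pred=(y, y))
        assert m.rmsec == 0.0 and m.r2c == 1.0
        assert m.rmsep == 0.0 and m.r2p == 1.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        yhat = np.full(4, y.mean())
        assert pf.r_squared(y, yhat) == pytest.approx(0.0)

    def test_hand_computed_three_element_case(self):
        y = np.array([1.0, 2.0, 4.0])
        yhat = np.array([1.5, 2.0, 3.0])
        # SSE = 0.25 + 0 + 1 = 1.25; RMSE = sqrt(1.25/3)
        assert pf.rmse(y, yhat) == pytest.approx(np.sqrt(1.25 / 3.0))
        # SST about mean 7/3: (16+1+25)/9 = 42/9
        assert pf.r_squared(y, yhat) == pytest.approx(1 - 1.25 / (42 / 9))

    def test_constant_truth_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            r2 = pf.r_squared(np.ones(5), np.zeros(5))
        assert np.isnan(r2)


class TestVip:
    def test_mean_squared_vip_is_one(self, rng):
        X = rng.normal(size=(40, 9))
        y = X @ rng.normal(size=9) + rng.normal(size=40)
        v = pf.vip_scores(pf.fit_plsr(X, y, 4))
        assert (v.scores**2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_single_informative_variable_scores_sqrt_p(self, rng):
        # one LV whose weight loads on a single variable among p=4
        n = 64
        x1 = rng.normal(size=n)
        x1 -= x1.mean()
        Q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        Q -= Q.mean(axis=0)
        resid = Q - x1[:, None] * (x1 @ Q) / (x1 @ x1)
        X = np.column_stack([x1, resid])
        y = x1.copy()
        v = pf.vip_scores(pf.fit_plsr(X, y, 1))
        assert v.scores[0] == pytest.approx(2.0, abs=1e-5)
        np.testing.assert_allclose(v.scores[1:], 0.0, atol=1e-5)

    def test_symmetric_weights_score_one(self, rng):
        # y loads equally on two standardized symmetric columns
        z = rng.normal(size=200)
        e = rng.normal(size=(200, 2)) * 1e-6
        X = np.column_stack([z + e[:, 0], z + e[:, 1]])
        y = X.sum(axis=1)
        v = pf.vip_scores(pf.fit_plsr(X, y, 1))
        np.testing.assert_allclose(v.scores, 1.0, atol=1e-3)

    def test_selected_uses_strict_threshold(self):
        v = pf.VIPResult(("a", "b", "c", "d"),
                         np.array([1.2, 0.9, 1.0, 1.5]))
        assert v.selected(1.0) == ["a", "d"]
        assert v.selected(0.0) == ["a", "b", "c", "d"]


class TestPlsdaVip:
    def test_discriminating_variable_is_top(self, rng):
        n = 60
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6))
        X[:, 2] += labels * 4.0
        v = pf.plsda_vip(X, labels, n_lv=2)
        assert int(np.argmax(v.scores)) == 2
        assert (v.scores**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_permuted_labels_flatten_profile(self, rng):
        n = 200
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6))
        X[:, 2] += labels * 4.0
        sharp = pf.plsda_vip(X, labels, n_lv=2)
        flat = pf.plsda_vip(X, rng.permutation(labels), n_lv=2)
        assert sharp.scores.max() > 1.5
        assert flat.scores.max() < sharp.scores.max()

    def test_single_class_rejected(self, rng):
        with pytest.raises(DomainError):
            pf.plsda_vip(rng.normal(size=(10, 3)), [1] * 10)


class TestPearsonPattern:
    def test_exact_correlations(self, rng):
        m = pd.DataFrame(
            {"day": 1, "replicate": 1,
             "a": rng.normal(size=30), "b": rng.normal(size=30)}
        )
        out = pf.pearson_pattern(m, 2.0 * m["a"])
        row = out.set_index("variable")
        assert row.loc["a", "r"] == pytest.approx(1.0)
        out_neg = pf.pearson_pattern(m, -m["b"])
        assert out_neg.set_index("variable").loc["b", "r"] == pytest.approx(-1.0)

    def test_sorted_by_absolute_r(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        t = m["a"] - 0.5 * m["b"]
        out = pf.pearson_pattern(m, t)
        assert (out["r"].abs().diff().dropna() <= 1e-12).all()

    def test_null_simulation_small_r(self):
        rng = np.random.default_rng(123)
        m = pd.DataFrame(rng.normal(size=(1000, 5)),
                         columns=list("abcde"))
        out = pf.pearson_pattern(m, rng.normal(size=1000))
        assert out["r"].abs().max() < 0.12

    def test_zero_variance_metabolite_gives_nan(self, rng):
        m = pd.DataFrame({"a": np.ones(10), "b": rng.normal(size=10)})
        out = pf.pearson_pattern(m, rng.normal(size=10))
        assert np.isnan(out.set_index("variable").loc["a", "r"])

    def test_too_few_observations(self):
        m = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(DomainError):
            pf.pearson_pattern(m, np.array([1.0, 2.0]))


def test_metricset_layout():
    m = MetricSet(rmsec=0.1, r2c=0.9)
    d = m.as_dict()
    assert list(d) == ["RMSEC", "RMSECV", "RMSEP", "R2C", "R2CV", "R2P"]
    assert np.isnan(d["R2P"])
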