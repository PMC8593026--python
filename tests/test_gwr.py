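"""OLS baseline and GWR: kernel arithmetic, WLS oracles, bandwidth selection."""

import numpy as np
import pytest
from sklearn.base import clone

from urbannpp import (
    GWRegressor,
    bisquare_weight,
    compare_models,
    fit_ols,
    select_bandwidth,
    summarize_gwr,
)
from urbannpp.gwr import OlsResult
from conftest import brute_force_wls


def toy_problem(n_side=10, seed=0, het=True, noise=0.5):
    """Small spatial regression problem with known local slope surface."""
    rng = np.random.default_rng(seed)
    xx, yy = np.meshgrid(np.arange(n_side, dtype=float),
                         np.arange(n_side, dtype=float))
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    x = rng.normal(size=n_side * n_side)
    slope = 1.0 + (coords[:, 0] / n_side if het else 0.0)
    y = 2.0 + slope * x + noise * rng.normal(size=x.size)
    return coords, x, y, slope


class TestBisquare:
    @pytest.mark.parametrize("d,b,expected", [(0.0, 2.0, 1.0),
                                              (2.0, 2.0, 0.0),
                                              (1.0, 2.0, 0.5625),
                                              (5.0, 2.0, 0.0)])
    def test_closed_form(self, d, b, expected):
        assert bisquare_weight(d, b) == pytest.approx(expected)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            bisquare_weight(1.0, 0.0)

    def test_non_increasing_in_distance(self):
        d = np.linspace(0, 3, 50)
        w = bisquare_weight(d, 2.0)
        assert np.all(np.diff(w) <= 1e-15)


class TestOls:
    def test_exact_linear_fit(self):
        x = np.arange(20.0)
        res = fit_ols(2 * x, x, names=["x"])
        assert res.coef[0] == pytest.approx(0.0, abs=1e-10)
        assert res.coef[1] == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        res = fit_ols(y, X)
        Xd = np.column_stack([np.ones(30), X])
        np.testing.assert_allclose(res.coef, brute_force_wls(Xd, y, np.ones(30)),
                                   rtol=0, atol=1e-10)
        assert res.tvalues[1] == pytest.approx(res.coef[1] / res.stderr[1])
        assert res.adj_r2 <= res.r2

    def test_collinear_column_named(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(rng.normal(size=25), X, names=["a", "b"])

    def test_null_slope_pvalues_are_uniform(self):
        """Under independence the slope p-value should be U(0,1)-distributed."""
        rng = np.random.default_rng(6)
        pvals = [fit_ols(rng.normal(size=40), rng.normal(size=40)).pvalues[1]
                 for _ in range(200)]
        # Kolmogorov-Smirnov against uniform at a generous level
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestGwrSolves:
    def test_local_solution_matches_brute_force_wls(self):
        coords, x, y, _ = toy_problem(n_side=7, seed=1)
        model = GWRegressor(bandwidth=15).fit(np.column_stack([coords, x]), y)
        Xd = np.column_stack([np.ones(x.size), x])
        for i in (0, 10, 24, 48):
            d = np.hypot(*(coords - coords[i]).T)
            b = np.partition(d, 14)[14]
            w = bisquare_weight(d, b)
            np.testing.assert_allclose(model.local_coef_[i],
                                       brute_force_wls(Xd, y, w),
                                       rtol=0, atol=1e-10)

    def test_huge_bandwidth_converges_to_ols(self):
        coords, x, y, _ = toy_problem(n_side=8, seed=2, het=False)
        diam = np.hypot(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]))
        model = GWRegressor(bandwidth=1e5 * diam, adaptive=False).fit(
            np.column_stack([coords, x]), y)
        ols = fit_ols(y, x)
        assert np.abs(model.local_coef_ - ols.coef).max() < 1e-6
        assert np.abs(model.fitted_ - ols.fitted).max() < 1e-6

    def test_exact_linear_response_equals_ols_at_any_bandwidth(self):
        coords, x, _, _ = toy_problem(n_side=8, seed=3)
        y = 2.0 + 3.0 * x
        model = GWRegressor(bandwidth=20).fit(np.column_stack([coords, x]), y)
        np.testing.assert_allclose(model.local_coef_[:, 0], 2.0, atol=1e-8)
        np.testing.assert_allclose(model.local_coef_[:, 1], 3.0, atol=1e-8)

    def test_hat_trace_and_residual_band(self):
        coords, x, y, _ = toy_problem(n_side=8, seed=4)
        model = GWRegressor(bandwidth=20).fit(np.column_stack([coords, x]), y)
        assert 2.0 < model.tr_S_ < len(y)
        assert np.isfinite(model.std_residuals_).all()
        pct = summarize_gwr(model, 1)["pct_stdres_in_band"]
        assert 0.0 <= pct <= 100.0

    def test_predict_at_training_locations_matches_fitted(self):
        coords, x, y, _ = toy_problem(n_side=6, seed=8)
        X = np.column_stack([coords, x])
        model = GWRegressor(bandwidth=12).fit(X, y)
        np.testing.assert_allclose(model.predict(X), model.fitted_, atol=1e-8)

    def test_sklearn_protocol(self):
        model = GWRegressor(bandwidth=10, criterion="cv")
        params = model.get_params()
        assert params["bandwidth"] == 10 and params["criterion"] == "cv"
        cloned = clone(model)
        assert cloned.get_params() == params


class TestBandwidthSelection:
    def test_golden_matches_exhaustive_grid(self):
        coords, x, y, _ = toy_problem(n_side=7, seed=5)
        k_g, prof_g = select_bandwidth(coords, x, y, search="golden")
        k_e, prof_e = select_bandwidth(coords, x, y, search="grid")
        assert prof_e[k_g] <= min(prof_e.values()) + 1e-6 or k_g == k_e

    def test_homogeneous_data_selects_wide_bandwidth(self):
        coords, x, y, _ = toy_problem(n_side=8, seed=6, het=False, noise=1.0)
        k, _ = select_bandwidth(coords, x, y, search="grid")
        assert k > 0.8 * len(y)

    def test_heterogeneous_city_prefers_local_model(self, default_city_grid):
        grid = default_city_grid
        y = grid.table["npp_ind"].to_numpy()
        x = grid.table["lst_t1"].to_numpy()
        model = GWRegressor().fit(np.column_stack([grid.coords, x]), y)
        ols = fit_ols(y, x, names=["lst"])
        assert model.bandwidth_ < len(y) / 2
        assert model.aic_ < ols.aic - 3

    def test_empty_range_rejected(self):
        coords, x, y, _ = toy_problem(n_side=4, seed=7)
        with pytest.raises(ValueError, match="range"):
            select_bandwidth(coords, x, y, k_range=(100, 10))


class TestSummariesAndComparison:
    def _fake_model(self, coefs, stdres):
        m = GWRegressor(bandwidth=5)
        n = len(coefs)
        m.local_coef_ = np.column_stack([np.zeros(n), np.asarray(coefs, float)])
        m.local_stderr_ = np.ones((n, 2))
        m.valid_ = np.ones(n, bool)
        m.std_residuals_ = np.asarray(stdres, float)
        m.coef_names_ = ["intercept", "x0"]
        return m

    def test_coefficient_share_arithmetic(self):
        m = self._fake_model([-1.0, -1.0, 2.0, 4.0], [0.1, -0.2, 0.3, 2.0])
        s = summarize_gwr(m, 1)
        assert s["min"] == -1.0 and s["max"] == 4.0 and s["mean"] == 1.0
        assert s["pct_positive"] == 50.0 and s["pct_negative"] == 50.0
        assert s["pct_stdres_in_band"] == 100.0

    def test_unknown_coefficient_rejected(self):
        m = self._fake_model([1.0], [0.0])
        with pytest.raises(KeyError, match="unknown"):
            summarize_gwr(m, "elevation")

    @pytest.mark.parametrize("aic_ols,aic_gwr,verdict", [
        (134948.273, 130634.719, "GWR preferred"),
        (100.0, 98.0, "indistinguishable"),
        (98.0, 100.0, "indistinguishable"),
        (100.0, 100.0, "indistinguishable"),
        (98.0, 110.0, "OLS preferred"),
    ])
    def test_delta_aic_verdicts(self, aic_ols, aic_gwr, verdict):
        ols = OlsResult(names=["intercept", "x"], coef=np.zeros(2),
                        stderr=np.ones(2), tvalues=np.zeros(2),
                        pvalues=np.ones(2), residuals=np.zeros(4),
                        fitted=np.zeros(4), r2=0.0, adj_r2=0.0,
                        aic=aic_ols, n=4)
        m = self._fake_model([1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0])
        m.aic_ = aic_gwr
        m.adj_r2_ = 0.5
        m.y_ = np.zeros(4)
        comp = compare_models(ols, m)
        assert comp["verdict"] == verdict
        assert comp["delta_aic"] == pytest.approx(aic_gwr - aic_ols)

    def test_mismatched_support_rejected(self):
        ols = OlsResult(names=["intercept", "x"], coef=np.zeros(2),
                        stderr=np.ones(2), tvalues=np.zeros(2),
                        pvalues=np.ones(2), residuals=np.zeros(9),
                        fitted=np.zeros(9), r2=0.0, adj_r2=0.0, aic=1.0, n=9)
        m = self._fake_model([1.0] * 4, [0.0] * 4)
        m.aic_ = 0.0
        m.adj_r2_ = 0.0
        m.y_ = np.zeros(4)
        with pytest.raises(ValueError, match="support"):
            compare_models(ols, m)
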