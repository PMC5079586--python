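"""Trend models: binomial GLM vs a Newton–Raphson oracle, the profiled
random-intercept model vs statsmodels, and the parametric bootstrap."""

import numpy as np
import pandas as pd
import pytest

from lenassess.core_data import LengthDataset
from lenassess.trends import (counts_from_percent, fit_binomial_trend,
                              fit_mixed_trend, parametric_bootstrap_test)


def newton_logistic(successes, totals, x, tol=1e-12, max_iter=200):
    """Independent IRLS-free oracle: straight Newton–Raphson on the
    binomial log-likelihood with design [1, x]."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (successes - totals * p)
        W = totals * p * (1 - p)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _sim_ds(slope, n_per, n_sources=5, years=range(1990, 2012), seed=0,
            source_sd=3.0, resid_sd=8.0, mu=55.0):
    rng = np.random.default_rng(seed)
    rows = []
    offsets = rng.normal(0, source_sd, n_sources)
    for year in years:
        for s in range(n_sources):
            tl = (mu + slope * (year - 2000) + offsets[s]
                  + rng.normal(0, resid_sd, n_per))
            rows.append(pd.DataFrame(
                {"year": year, "source": f"src{s}", "tl_cm": np.abs(tl) + 0.1}))
    return LengthDataset(pd.concat(rows, ignore_index=True))


class TestBinomialTrend:
    def test_flat_proportions_give_zero_slope(self):
        totals = np.array([100, 200, 100, 400])
        succ = totals // 4
        fit = fit_binomial_trend(succ, totals, [2000, 2001, 2002, 2003])
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert fit.lr_chisq == pytest.approx(0.0, abs=1e-6)
        assert fit.p_value > 0.99

    def test_matches_newton_oracle(self):
        """Coefficients agree with an independent Newton–Raphson fit to 1e-8."""
        years = np.array([1983.0, 1998.0, 2003.0, 2012.0])
        succ = np.array([223.0, 79.0, 25.0, 21.0])
        totals = np.array([1299.0, 544.0, 191.0, 489.0])
        fit = fit_binomial_trend(succ, totals, years)
        yc = years - years.mean()
        beta = newton_logistic(succ, totals, yc)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.slope == pytest.approx(beta[1], abs=1e-8)

    def test_lr_invariant_to_year_recentering(self):
        succ = [50, 40, 30, 10]
        totals = [100, 100, 100, 100]
        a = fit_binomial_trend(succ, totals, [2000, 2001, 2002, 2003])
        b = fit_binomial_trend(succ, totals, [0, 1, 2, 3])
        assert a.lr_chisq == pytest.approx(b.lr_chisq, rel=1e-8)
        assert a.slope == pytest.approx(b.slope, rel=1e-8)

    def test_separation_flagged(self):
        fit = fit_binomial_trend([0, 0, 100, 100], [100, 100, 100, 100],
                                 [2000, 2001, 2002, 2003])
        assert fit.separated

    def test_counts_from_percent_roundtrip(self):
        n = np.array([1299, 489])
        pct = np.array([17.2, 4.3])
        counts = counts_from_percent(pct, n)
        assert counts.tolist() == [223, 21]

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_binomial_trend([1, 2], [10, 10], [2000, 2001])
        with pytest.raises(ValueError):
            fit_binomial_trend([11, 2, 3], [10, 10, 10], [2000, 2001, 2002])


class TestMixedTrend:
    def test_zero_source_variance_reduces_to_ols(self):
        """Data with no among-source spread: slope equals the OLS slope."""
        ds = _sim_ds(-0.25, n_per=40, source_sd=0.0, seed=2)
        fit = fit_mixed_trend(ds)
        y = ds.df["tl_cm"].to_numpy()
        x = ds.df["year"].to_numpy(float)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert fit.slope == pytest.approx(ols_slope, abs=1e-6)
        assert fit.source_sd < 0.5

    def test_recovers_simulated_slope_within_2se(self):
        """Median standardised error over replicate simulations stays inside
        2 se (a single draw trips the 2-se band ~5% of the time by design)."""
        zs = []
        for seed in (7, 8, 9):
            ds = _sim_ds(-0.25, n_per=20, seed=seed)  # 5 sources, 22 yrs
            fit = fit_mixed_trend(ds)
            zs.append(abs(fit.slope - (-0.25)) / fit.slope_se)
        assert np.median(zs) < 2.0

    def test_agrees_with_statsmodels_mixedlm(self):
        """Profiled-ML implementation vs statsmodels MixedLM (ML): slope,
        its SE, and the variance components."""
        import statsmodels.formula.api as smf
        ds = _sim_ds(-0.3, n_per=10, n_sources=4, seed=11)
        fit = fit_mixed_trend(ds)
        df = ds.df.assign(yc=ds.df["year"] - ds.df["year"].mean())
        sm_fit = smf.mixedlm("tl_cm ~ yc", df, groups=df["source"]).fit(reml=False)
        assert fit.slope == pytest.approx(sm_fit.params["yc"], abs=1e-5)
        assert fit.slope_se == pytest.approx(sm_fit.bse["yc"], rel=1e-3)
        assert fit.resid_sd ** 2 == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_single_source_falls_back_with_flag(self):
        ds = _sim_ds(-0.25, n_per=20, n_sources=1, seed=3)
        fit = fit_mixed_trend(ds)
        assert fit.single_source


class TestParametricBootstrap:
    def test_null_data_not_significant(self):
        ds = _sim_ds(0.0, n_per=8, seed=13)
        res = parametric_bootstrap_test(ds, n_boot=99, seed=5)
        assert res.pb_p > 0.05

    def test_effect_detected_and_p_floor(self):
        ds = _sim_ds(-0.5, n_per=20, seed=19)
        res = parametric_bootstrap_test(ds, n_boot=19, seed=5)
        assert res.pb_p >= 1.0 / 20.0  # plus-one rule: never exactly 0
        assert res.pb_p == pytest.approx(1.0 / 20.0)
        assert res.pb_stat > 10

    def test_seed_fixes_the_resample_stream(self):
        ds = _sim_ds(-0.2, n_per=6, seed=23)
        a = parametric_bootstrap_test(ds, n_boot=30, seed=1)
        b = parametric_bootstrap_test(ds, n_boot=30, seed=1)
        assert a.pb_p == b.pb_p and a.pb_stat == b.pb_stat
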