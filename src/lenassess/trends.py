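"""Year-trend inference for indicator proportions and landed length.

Two model families:

* Binomial GLMs (logit link) of per-year indicator counts against calendar
  year, fit by iteratively reweighted least squares through statsmodels;
  significance is a likelihood-ratio chi-square against the intercept-only
  model.
* A normal random-intercept model of individual landed length,
  ``TL ~ year + (1 | source)``, fit by maximum likelihood with the single
  variance ratio profiled out (a one-dimensional optimisation; fixed
  effects and the residual variance have closed forms given the ratio).
  Significance of the year effect comes from a parametric bootstrap of the
  likelihood-ratio statistic: the null (no-year) fit simulates replicate
  datasets, both models are refit to each, and the p-value is
  ``(1 + #{boot LR >= observed}) / (n_boot + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .core_data import LengthDataset

logger = logging.getLogger(__name__)


@dataclass
class BinomialTrendFit:
    """Logistic regression of a proportion on calendar year."""

    slope: float          # logit units per calendar year
    intercept: float      # logit value at the mean year
    lr_chisq: float
    p_value: float
    n_years: int
    separated: bool = False

    def __post_init__(self) -> None:
        if self.lr_chisq < -1e-8:
            raise ValueError("LR statistic must be nonnegative")


@dataclass
class MixedTrendFit:
    """Random-intercept (by data source) trend of landed length on year."""

    slope: float          # cm per calendar year
    slope_se: float
    intercept: float      # cm at the mean year
    source_sd: float      # among-source sd (cm)
    resid_sd: float       # residual sd (cm)
    loglik: float
    n_sources: int
    single_source: bool = False
    pb_stat: float | None = None
    pb_p: float | None = None
    n_boot: int = 0
    n_boot_failed: int = 0


def fit_binomial_trend(successes, totals, years) -> BinomialTrendFit:
    """Binomial GLM of per-year counts on year, with an LR test vs. null.

    Years are centred internally for conditioning; the reported slope is
    per calendar year (centring leaves it unchanged).  Complete separation
    is flagged, with the (divergent) estimates still reported.
    """
    successes = np.asarray(successes, float)
    totals = np.asarray(totals, float)
    years = np.asarray(years, float)
    if len(years) < 3:
        raise ValueError("need at least 3 years")
    if np.any(successes < 0) or np.any(successes > totals):
        raise ValueError("require 0 <= successes <= totals")

    yc = years - years.mean()
    endog = np.column_stack([successes, totals - successes])
    exog = sm.add_constant(yc)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    try:
        res = model.fit(tol=1e-10, maxiter=200)
        separated = not np.all(np.isfinite(res.bse)) or np.any(
            np.abs(res.params) > 50)
    except Exception:  # perfectly separated data can break IRLS outright
        logger.warning("binomial trend: IRLS failed; refitting regularised")
        res = model.fit_regularized(alpha=1e-8)
        separated = True
    lr = float(res.null_deviance - res.deviance)
    lr = max(lr, 0.0)
    if separated:
        logger.warning("binomial trend: complete separation suspected")
    return BinomialTrendFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        lr_chisq=lr, p_value=float(chi2.sf(lr, df=1)),
        n_years=len(years), separated=separated)


def counts_from_percent(pct, n) -> np.ndarray:
    """Reconstruct integer successes from printed percentages.

    ``round(pct * n / 100)`` — the inverse of a count-then-round report.
    Only approximate when the source percentages were themselves rounded.
    """
    pct = np.asarray(pct, float)
    n = np.asarray(n, float)
    return np.round(pct * n / 100.0).astype(int)


# ---------------------------------------------------------------------------
# random-intercept model, profiled maximum likelihood

def _group_structure(ds: LengthDataset):
    y = ds.df["tl_cm"].to_numpy(float)
    yr = ds.df["year"].to_numpy(float)
    codes, _ = pd.factorize(ds.df["source"])
    return y, yr, codes


def _profile_loglik(lam: float, y: np.ndarray, x: np.ndarray,
                    codes: np.ndarray, n_groups: int):
    """ML profile log-likelihood at variance ratio lam = var_b / var_e.

    With V0 = I + lam·ZZ' (Z the source-indicator matrix), the inverse is
    block-wise I − c_g·1·1' with c_g = lam/(1 + m_g·lam), so all GLS
    quantities reduce to per-group sums.  Returns (loglik, beta, sigma_e2,
    cov_beta_unscaled).
    """
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    m_g = np.bincount(codes, minlength=n_groups).astype(float)
    c_g = lam / (1.0 + m_g * lam)

    sx = np.column_stack([
        np.bincount(codes, minlength=n_groups),
        np.bincount(codes, weights=x, minlength=n_groups)])
    sy = np.bincount(codes, weights=y, minlength=n_groups)
    xtvx = X.T @ X - (sx * c_g[:, None]).T @ sx
    xtvy = X.T @ y - (sx * c_g[:, None]).T @ sy
    beta = np.linalg.solve(xtvx, xtvy)
    r = y - X @ beta
    sr = np.bincount(codes, weights=r, minlength=n_groups)
    q = float(r @ r - np.sum(c_g * sr**2))
    sigma_e2 = q / n
    logdet = float(np.sum(np.log1p(m_g * lam)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma_e2) + logdet + n)
    return ll, beta, sigma_e2, np.linalg.inv(xtvx)


def _fit_profiled(y, x, codes) -> dict:
    n_groups = int(codes.max()) + 1
    def neg(log_lam):
        return -_profile_loglik(np.exp(log_lam), y, x, codes, n_groups)[0]
    # bracket on log-lambda; include the lam -> 0 boundary explicitly
    res = minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-8})
    ll0, *_ = _profile_loglik(0.0, y, x, codes, n_groups)
    if -res.fun >= ll0:
        lam = float(np.exp(res.x))
        ll = -float(res.fun)
    else:
        lam, ll = 0.0, float(ll0)
    _, beta, sigma_e2, cov_u = _profile_loglik(lam, y, x, codes, n_groups)
    return {"lam": lam, "loglik": ll, "beta": beta, "sigma_e2": sigma_e2,
            "cov_beta": sigma_e2 * cov_u, "n_groups": n_groups}


def fit_mixed_trend(ds: LengthDataset) -> MixedTrendFit:
    """ML fit of ``TL ~ year + (1 | source)``.

    The among-source variance absorbs systematic level differences between
    datasets collected by different programmes and methods, so the year
    slope is not driven by which source happened to sample which years.
    With a single source the model degenerates to ordinary regression
    (fitted with a warning and ``single_source=True``).
    """
    if len(ds) < 3:
        raise ValueError("need at least 3 records")
    y, yr, codes = _group_structure(ds)
    if len(np.unique(yr)) < 3:
        raise ValueError("need at least 3 distinct years")
    yc = yr - yr.mean()
    n_sources = int(codes.max()) + 1
    single = n_sources < 2
    if single:
        logger.warning("fit_mixed_trend: single source; plain regression")
    fit = _fit_profiled(y, yc, codes)
    sigma_e = float(np.sqrt(fit["sigma_e2"]))
    sigma_b = float(np.sqrt(fit["lam"] * fit["sigma_e2"]))
    return MixedTrendFit(
        slope=float(fit["beta"][1]),
        slope_se=float(np.sqrt(fit["cov_beta"][1, 1])),
        intercept=float(fit["beta"][0]),
        source_sd=sigma_b, resid_sd=sigma_e,
        loglik=fit["loglik"], n_sources=n_sources, single_source=single)


def _loglik_null(y, codes) -> dict:
    """Null model TL ~ 1 + (1|source): same machinery, constant regressor."""
    n_groups = int(codes.max()) + 1
    def neg(log_lam):
        lam = np.exp(log_lam)
        return -_profile_loglik_null(lam, y, codes, n_groups)[0]
    res = minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-8})
    ll0, *_ = _profile_loglik_null(0.0, y, codes, n_groups)
    if -res.fun >= ll0:
        lam, ll = float(np.exp(res.x)), -float(res.fun)
    else:
        lam, ll = 0.0, float(ll0)
    _, mu, sigma_e2 = _profile_loglik_null(lam, y, codes, n_groups)
    return {"lam": lam, "loglik": ll, "mu": mu, "sigma_e2": sigma_e2,
            "n_groups": n_groups}


def _profile_loglik_null(lam, y, codes, n_groups):
    n = len(y)
    m_g = np.bincount(codes, minlength=n_groups).astype(float)
    c_g = lam / (1.0 + m_g * lam)
    sy = np.bincount(codes, weights=y, minlength=n_groups)
    denom = float(n - np.sum(c_g * m_g**2))
    mu = float((y.sum() - np.sum(c_g * m_g * sy)) / denom)
    r = y - mu
    sr = sy - mu * m_g
    q = float(r @ r - np.sum(c_g * sr**2))
    sigma_e2 = q / n
    logdet = float(np.sum(np.log1p(m_g * lam)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma_e2) + logdet + n)
    return ll, mu, sigma_e2


def parametric_bootstrap_test(ds: LengthDataset, n_boot: int = 1000,
                              seed: int = 0) -> MixedTrendFit:
    """Parametric-bootstrap LR test of the year effect on landed length.

    Observed statistic: ``2 (loglik_full − loglik_null)``.  Replicates are
    simulated from the fitted null model (new source intercepts and
    residuals each draw), both models refit, and
    ``p = (1 + #{boot >= obs}) / (n_boot + 1)`` — never exactly zero.
    Replicates whose refit fails numerically are dropped and counted; more
    than 10% failures triggers a warning.
    """
    full = fit_mixed_trend(ds)
    y, yr, codes = _group_structure(ds)
    yc = yr - yr.mean()
    null = _loglik_null(y, codes)
    obs = 2.0 * (full.loglik - null["loglik"])

    sigma_e = np.sqrt(null["sigma_e2"])
    sigma_b = np.sqrt(null["lam"] * null["sigma_e2"])
    rng = np.random.default_rng(seed)
    n_groups = null["n_groups"]
    stats, failed = [], 0
    for _ in range(n_boot):
        b = rng.normal(0.0, sigma_b, size=n_groups)
        y_star = null["mu"] + b[codes] + rng.normal(0.0, sigma_e, size=len(y))
        try:
            fit_f = _fit_profiled(y_star, yc, codes)
            fit_n = _loglik_null(y_star, codes)
            stats.append(2.0 * (fit_f["loglik"] - fit_n["loglik"]))
        except (np.linalg.LinAlgError, ValueError):
            failed += 1
    if n_boot and failed > 0.1 * n_boot:
        logger.warning("parametric bootstrap: %d/%d refits failed",
                       failed, n_boot)
    n_ok = len(stats)
    p = (1.0 + np.sum(np.asarray(stats) >= obs - 1e-10)) / (n_ok + 1.0)
    full.pb_stat = float(obs)
    full.pb_p = float(p)
    full.n_boot = n_ok
    full.n_boot_failed = failed
    return full
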