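"""Length-based spawning-potential-ratio (LB-SPR) per-recruit engine.

The model world is an equilibrium, per-recruit population: constant
recruitment, von Bertalanffy growth with among-individual variability in
L∞, natural mortality M, and fishing mortality F applied through an
asymptotic logistic selectivity curve.  From length-composition data alone
(plus the life-history ratios M/k, L∞ and CV L∞) the engine

* predicts the expected catch length composition for any (F/M, SL50, SL95),
* estimates those three parameters by maximising a multinomial likelihood
  over the observed composition, and
* converts any parameter set into a Spawning Potential Ratio — lifetime
  egg production per recruit under fishing divided by the unfished value.

Growth variability is propagated with *growth-type groups*: discrete
sub-cohorts whose L∞ values sit at equally spaced points of the normal
distribution N(L∞, CV·L∞) truncated at ±2.5 sd, weighted by the normal
density.  Within each group, length-at-age is normal around the group's
growth curve with the residual spread that keeps the marginal
length-at-age CV equal to ``cv_linf`` regardless of the number of groups
(a single group therefore carries the full CV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .core_data import LifeHistory

logger = logging.getLogger(__name__)

LN19 = np.log(19.0)

#: Conventional growth-type-group defaults.
N_GTG_DEFAULT = 13
MAX_SD_DEFAULT = 2.5

#: Default length-bin width (cm) and grid span as a multiple of L∞.
BIN_WIDTH_DEFAULT = 2.0
GRID_SPAN_DEFAULT = 1.3


@dataclass(frozen=True)
class SelectivityParams:
    """Asymptotic logistic gear selectivity, anchored at 50% and 95%."""

    sl50: float
    sl95: float

    def __post_init__(self) -> None:
        if not (0 < self.sl50 < self.sl95):
            raise ValueError(
                f"require 0 < sl50 < sl95, got ({self.sl50}, {self.sl95})")

    def at_length(self, l: np.ndarray | float) -> np.ndarray | float:
        return logistic_ogive(l, self.sl50, self.sl95)


def logistic_ogive(l: np.ndarray | float, l50: float, l95: float):
    """Two-anchor logistic: value 0.5 at ``l50`` and 0.95 at ``l95``.

    ``1 / (1 + exp(-ln(19) * (l - l50) / (l95 - l50)))`` — the standard
    parameterisation of maturity and selectivity ogives in length-based
    assessment.
    """
    if not l95 > l50:
        raise ValueError(f"require l95 > l50, got ({l50}, {l95})")
    return expit(LN19 * (np.asarray(l, float) - l50) / (l95 - l50))


def selectivity_at_length(l: np.ndarray | float, sel: SelectivityParams):
    """Probability a fish of length ``l`` (cm) is captured by the gear."""
    return logistic_ogive(l, sel.sl50, sel.sl95)


def maturity_at_length(l: np.ndarray | float, lh: LifeHistory):
    """Proportion mature at length ``l`` (cm) from the (lm50, lm95) ogive."""
    return logistic_ogive(l, lh.lm50, lh.lm95)


@dataclass
class LengthComposition:
    """Binned length-frequency data on a half-open grid [lo, hi).

    ``counts`` may be observed integers or expected (real) masses; the
    ``proportions`` view is always normalised to sum to one.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.counts = np.asarray(self.counts, float)
        if self.bin_edges.ndim != 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing 1-D")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have len(bin_edges) - 1 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_lengths(
        cls,
        lengths: Sequence[float] | np.ndarray,
        bin_width: float = BIN_WIDTH_DEFAULT,
        l_max: float | None = None,
    ) -> "LengthComposition":
        """Bin raw lengths into half-open bins [0, w), [w, 2w), ...."""
        lengths = np.asarray(lengths, float)
        if l_max is None:
            l_max = float(lengths.max()) + bin_width
        n_bins = int(np.ceil(l_max / bin_width))
        edges = np.arange(n_bins + 1) * bin_width
        # np.histogram's last bin is closed; pad so every fish lands half-open
        counts, _ = np.histogram(lengths, bins=np.append(edges, edges[-1] + bin_width))
        return cls(edges, counts[:-1])

    @property
    def mids(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot <= 0:
            raise ValueError("empty composition has no proportions")
        return self.counts / tot

    def mean_length(self) -> float:
        return float(np.sum(self.mids * self.proportions))


@dataclass
class PerRecruitQuantities:
    """Per-recruit bookkeeping behind an SPR value.

    ``ages``, ``e_at_age`` and ``z_at_age`` refer to the central
    growth-type group (the mean-L∞ growth curve); ``p_fished``,
    ``p_unfished`` and ``spr`` aggregate over all groups with their
    quantile weights.
    """

    ages: np.ndarray
    e_at_age: np.ndarray
    z_at_age: np.ndarray
    p_fished: float
    p_unfished: float
    spr: float

    def __post_init__(self) -> None:
        if self.p_unfished <= 0:
            raise ValueError("p_unfished must be positive")
        if not (0.0 <= self.spr <= 1.0 + 1e-12):
            raise ValueError(f"spr out of [0, 1]: {self.spr}")


def default_bin_edges(lh: LifeHistory,
                      bin_width: float = BIN_WIDTH_DEFAULT,
                      span: float = GRID_SPAN_DEFAULT) -> np.ndarray:
    """Half-open length grid from 0 to ``span``·L∞ in ``bin_width`` steps."""
    top = span * lh.l_inf
    n_bins = int(np.ceil(top / bin_width))
    return np.arange(n_bins + 1) * bin_width


def growth_type_groups(lh: LifeHistory,
                       n_gtg: int = N_GTG_DEFAULT,
                       max_sd: float = MAX_SD_DEFAULT
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Discretise the L∞ distribution into weighted growth-type groups.

    Returns ``(l_inf_g, weights, within_cv)`` where the group L∞ values sit
    at ``n_gtg`` equally spaced points spanning ±``max_sd`` standard
    deviations of N(L∞, cv_linf·L∞) with normalised normal-density weights,
    and ``within_cv`` is the residual within-group CV chosen so the
    marginal length-at-age CV equals ``cv_linf``:
    ``within_cv = cv_linf * sqrt(1 - var_w(x))`` with ``x`` the
    standardised group offsets.  With one group the full CV is within-group.
    """
    if n_gtg < 1:
        raise ValueError("n_gtg must be >= 1")
    if n_gtg == 1 or lh.cv_linf == 0:
        return np.array([lh.l_inf]), np.array([1.0]), lh.cv_linf
    x = np.linspace(-max_sd, max_sd, n_gtg)
    w = norm.pdf(x)
    w = w / w.sum()
    var_x = float(np.sum(w * x**2) - np.sum(w * x) ** 2)
    within_cv = lh.cv_linf * np.sqrt(max(0.0, 1.0 - var_x))
    linfs = lh.l_inf * (1.0 + lh.cv_linf * x)
    return linfs, w, within_cv


def _ages(lh: LifeHistory, age_step: float) -> np.ndarray:
    tmax = lh.tmax if lh.tmax is not None else -np.log(0.01) / lh.m_nat
    return np.arange(0.0, tmax + age_step / 2, age_step)


def _survivorship(z_step: np.ndarray) -> np.ndarray:
    """Relative numbers-at-age from per-step total mortality (N_0 = 1)."""
    return np.concatenate([[1.0], np.exp(-np.cumsum(z_step[:-1]))])


def expected_length_composition(
    lh: LifeHistory,
    f_over_m: float,
    sel: SelectivityParams,
    bin_edges: np.ndarray | None = None,
    n_gtg: int = N_GTG_DEFAULT,
    max_sd: float = MAX_SD_DEFAULT,
    age_step: float = 1.0,
) -> LengthComposition:
    """Expected catch proportions per length bin under the per-recruit model.

    For each growth-type group the equilibrium numbers-at-age follow
    survivorship with total mortality ``Z_a = M + F·S(μ_a)`` evaluated at
    the group's mean length at age; catch-at-age is selectivity-weighted
    and spread over the length grid through each age's normal length
    distribution (truncated to the grid).  Groups combine with their
    quantile weights and the result is normalised to proportions.
    """
    if f_over_m < 0:
        raise ValueError("f_over_m must be >= 0")
    if bin_edges is None:
        bin_edges = default_bin_edges(lh)
    bin_edges = np.asarray(bin_edges, float)
    if len(bin_edges) < 3:
        raise ValueError("degenerate length grid: need at least 2 bins")

    linfs, weights, within_cv = growth_type_groups(lh, n_gtg, max_sd)
    ages = _ages(lh, age_step)
    M, F = lh.m_nat, f_over_m * lh.m_nat

    mass = np.zeros(len(bin_edges) - 1)
    for linf_g, w_g in zip(linfs, weights):
        mu = linf_g * np.maximum(
            0.0, 1.0 - np.exp(-lh.k_growth * (ages - lh.t0)))
        s_a = selectivity_at_length(np.maximum(mu, 1e-12), sel)
        numbers = _survivorship((M + F * s_a) * age_step)
        catch = numbers * s_a
        alive = mu > 0  # zero-length fish cannot appear in a catch
        if not np.any(alive):
            continue
        sd = np.maximum(within_cv * mu[alive], 1e-6)
        # P(bin | age): normal cdf differences, renormalised to the grid
        cdf = norm.cdf(bin_edges[None, :], loc=mu[alive, None],
                       scale=sd[:, None])
        p_bin = np.diff(cdf, axis=1)
        tot = p_bin.sum(axis=1, keepdims=True)
        np.divide(p_bin, tot, out=p_bin, where=tot > 0)
        mass += w_g * (catch[alive, None] * p_bin).sum(axis=0)

    total = mass.sum()
    if total <= 0:
        raise ValueError("no catch mass on the length grid")
    return LengthComposition(bin_edges, mass / total)


def per_recruit_quantities(
    lh: LifeHistory,
    f_over_m: float,
    sel: SelectivityParams,
    n_gtg: int = N_GTG_DEFAULT,
    max_sd: float = MAX_SD_DEFAULT,
    age_step: float = 1.0,
) -> PerRecruitQuantities:
    """Lifetime egg production per recruit, fished and unfished.

    Egg production at age is maturity at the mean length times the
    fecundity power law ``length**fec_b``; fished survivorship uses
    ``Z_a = M + F·S(μ_a)``, unfished survivorship ``exp(-M·a)``.  SPR is
    the ratio of the two weighted sums over growth-type groups.
    """
    if f_over_m < 0:
        raise ValueError("f_over_m must be >= 0")
    linfs, weights, _ = growth_type_groups(lh, n_gtg, max_sd)
    ages = _ages(lh, age_step)
    M, F = lh.m_nat, f_over_m * lh.m_nat

    p_fished = p_unfished = 0.0
    e_central = z_central = None
    central = int(np.argmax(weights))
    for i, (linf_g, w_g) in enumerate(zip(linfs, weights)):
        mu = linf_g * np.maximum(
            0.0, 1.0 - np.exp(-lh.k_growth * (ages - lh.t0)))
        s_a = selectivity_at_length(np.maximum(mu, 1e-12), sel)
        z_a = M + F * s_a
        n_f = _survivorship(z_a * age_step)
        n_u = np.exp(-M * ages)
        e_a = maturity_at_length(np.maximum(mu, 1e-12), lh) * mu ** lh.fec_b
        p_fished += w_g * float(np.sum(e_a * n_f)) * age_step
        p_unfished += w_g * float(np.sum(e_a * n_u)) * age_step
        if i == central:
            e_central, z_central = e_a, z_a
    spr = min(p_fished / p_unfished, 1.0)
    return PerRecruitQuantities(ages=ages, e_at_age=e_central,
                                z_at_age=z_central, p_fished=p_fished,
                                p_unfished=p_unfished, spr=spr)


def spawning_potential_ratio(
    lh: LifeHistory,
    f_over_m: float,
    sel: SelectivityParams,
    n_gtg: int = N_GTG_DEFAULT,
    age_step: float = 1.0,
) -> float:
    """SPR in [0, 1]: 1 when unfished, → 0 under severe overfishing."""
    return per_recruit_quantities(
        lh, f_over_m, sel, n_gtg=n_gtg, age_step=age_step).spr


@dataclass
class LBSPRFit:
    """Result of a maximum-likelihood LB-SPR fit.

    ``spr`` is only meaningful when ``converged`` is true; ``at_boundary``
    flags estimates pinned at F/M ≈ 0.  Bootstrap standard deviations are
    populated when the fit was run with ``n_boot > 0``.
    """

    f_over_m: float
    sel: SelectivityParams
    spr: float | None
    loglik: float
    converged: bool
    at_boundary: bool = False
    n_fish: float = 0.0
    sd_f_over_m: float | None = None
    sd_sl50: float | None = None
    sd_sl95: float | None = None
    sd_spr: float | None = None
    starts: list[dict] = field(default_factory=list, repr=False)


def _unpack(theta: np.ndarray) -> tuple[float, SelectivityParams]:
    fm = float(np.exp(np.clip(theta[0], -20, 5)))
    sl50 = float(theta[1])
    delta = float(np.exp(np.clip(theta[2], -10, 8)))
    return fm, SelectivityParams(max(sl50, 1e-3), max(sl50, 1e-3) + delta)


def _neg_loglik(theta: np.ndarray, obs: LengthComposition, lh: LifeHistory,
                n_gtg: int, age_step: float) -> float:
    try:
        fm, sel = _unpack(theta)
        pred = expected_length_composition(
            lh, fm, sel, obs.bin_edges, n_gtg=n_gtg, age_step=age_step)
    except (ValueError, FloatingPointError):
        return 1e12
    p = np.maximum(pred.counts, 1e-12)
    return -float(np.sum(obs.counts * np.log(p)))


def _default_starts(obs: LengthComposition, lh: LifeHistory) -> list[np.ndarray]:
    """Three deterministic starts anchored on observed length quantiles."""
    props = obs.proportions
    cum = np.cumsum(props)
    mids = obs.mids
    def q(p: float) -> float:
        return float(mids[np.searchsorted(cum, p, side="left").clip(0, len(mids) - 1)])
    q20, q35, q50 = q(0.2), q(0.35), q(0.5)
    spread = max(q(0.6) - q(0.2), 2.0)
    return [
        np.array([np.log(1.0), q20, np.log(spread)]),
        np.array([np.log(0.3), q35, np.log(spread)]),
        np.array([np.log(2.5), q50, np.log(spread)]),
    ]


def fit_lbspr(
    obs: LengthComposition,
    lh: LifeHistory,
    start: SelectivityParams | None = None,
    start_f_over_m: float = 1.0,
    n_gtg: int = N_GTG_DEFAULT,
    age_step: float = 1.0,
    n_boot: int = 0,
    seed: int | None = None,
) -> LBSPRFit:
    """Estimate (F/M, SL50, SL95) and SPR from a length composition.

    Maximises the multinomial log-likelihood of the observed bin counts
    under :func:`expected_length_composition`, searching over the
    transformed parameters (log F/M, SL50, log(SL95−SL50)) with a
    derivative-free simplex from three deterministic starts (or a single
    user-supplied start).  SPR is evaluated at the optimum.  With
    ``n_boot > 0``, standard deviations come from a nonparametric bootstrap
    that resamples individual fish (multinomial over bins) and refits from
    the point estimate.
    """
    if obs.n_total <= 0:
        raise ValueError("empty length composition")
    if np.count_nonzero(obs.counts) < 3:
        raise ValueError("need at least 3 non-empty length bins")
    if obs.n_total < 50:
        logger.warning("fit_lbspr: only %.0f fish; estimates will be noisy",
                       obs.n_total)

    if start is not None:
        starts = [np.array([np.log(max(start_f_over_m, 1e-6)), start.sl50,
                            np.log(start.sl95 - start.sl50)])]
    else:
        starts = _default_starts(obs, lh)

    args = (obs, lh, n_gtg, age_step)
    best, attempts = None, []
    for theta0 in starts:
        res = minimize(_neg_loglik, theta0, args=args, method="Nelder-Mead",
                       options={"fatol": 1e-6, "xatol": 1e-5,
                                "maxiter": 4000, "maxfev": 4000})
        attempts.append({"x0": theta0.tolist(), "fun": float(res.fun),
                         "success": bool(res.success)})
        if res.success and (best is None or res.fun < best.fun):
            best = res

    if best is None:
        logger.warning("fit_lbspr: no start converged")
        fm, sel_hat = _unpack(starts[0])
        return LBSPRFit(f_over_m=fm, sel=sel_hat, spr=None, loglik=np.nan,
                        converged=False, n_fish=obs.n_total, starts=attempts)

    fm_hat, sel_hat = _unpack(best.x)
    at_boundary = fm_hat < 1e-2
    spr_hat = spawning_potential_ratio(lh, fm_hat, sel_hat,
                                       n_gtg=n_gtg, age_step=age_step)
    fit = LBSPRFit(f_over_m=fm_hat, sel=sel_hat, spr=spr_hat,
                   loglik=-float(best.fun), converged=True,
                   at_boundary=at_boundary, n_fish=obs.n_total,
                   starts=attempts)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = int(round(obs.n_total))
        fms, s50s, s95s, sprs = [], [], [], []
        for _ in range(n_boot):
            counts_b = rng.multinomial(n, obs.proportions)
            obs_b = LengthComposition(obs.bin_edges, counts_b)
            res_b = minimize(_neg_loglik, best.x, args=(obs_b, lh, n_gtg, age_step),
                             method="Nelder-Mead",
                             options={"fatol": 1e-5, "xatol": 1e-4,
                                      "maxiter": 2000})
            if not res_b.success:
                continue
            fm_b, sel_b = _unpack(res_b.x)
            fms.append(fm_b)
            s50s.append(sel_b.sl50)
            s95s.append(sel_b.sl95)
            sprs.append(spawning_potential_ratio(
                lh, fm_b, sel_b, n_gtg=n_gtg, age_step=age_step))
        if len(fms) >= 2:
            fit.sd_f_over_m = float(np.std(fms, ddof=1))
            fit.sd_sl50 = float(np.std(s50s, ddof=1))
            fit.sd_sl95 = float(np.std(s95s, ddof=1))
            fit.sd_spr = float(np.std(sprs, ddof=1))
    return fit
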