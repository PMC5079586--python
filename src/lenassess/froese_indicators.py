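"""Froese catch-composition sustainability indicators.

Three simple indicators computed from size-at-landing data alone:

1. percentage of the catch at or above the length at 50% maturity (low
   values signal recruitment overfishing),
2. percentage within the optimum-length interval — ±10% around L_opt, the
   length at which an unfished cohort's biomass and yield per fish peak
   (low values signal growth overfishing), and
3. percentage of mega-spawners, fish longer than L_opt + 10% (a healthy,
   unregulated stock is expected to land roughly 30–40% of them).

L_opt comes from the empirical power law
``L_opt = 10 ** (1.0421 * log10(L_inf) - 0.2742)``.

Boundary conventions: maturity uses ``tl >= lm50``; the optimum interval
is closed ``[lo, hi]``; mega-spawners use strict ``tl > hi``.  Percentages
are carried at full precision and rounded only for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import LengthDataset, LifeHistory

logger = logging.getLogger(__name__)

#: Healthy-stock reference levels (configurable in assessments).
HEALTHY_PCT_MATURE = 100.0
HEALTHY_PCT_OPT = 90.0
HEALTHY_PCT_MEGA_RANGE = (30.0, 40.0)


@dataclass(frozen=True)
class OptimalLength:
    """Optimum harvest length with its ±10% interval.

    ``mega_threshold`` equals the upper bound ``hi`` by definition: a
    mega-spawner is any fish strictly longer than L_opt + 10%.
    """

    lopt: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.lopt < self.hi):
            raise ValueError("require 0 < lo < lopt < hi")

    @property
    def mega_threshold(self) -> float:
        return self.hi


@dataclass(frozen=True)
class FishClass:
    """Category flags for one fish."""

    mature: bool
    in_opt_interval: bool
    mega: bool


@dataclass(frozen=True)
class HealthFlags:
    """Red flags derived from one indicator row against reference levels."""

    recruitment_overfishing: bool
    growth_overfishing: bool
    mega_spawner_deficit: bool


def compute_lopt(l_inf: float) -> OptimalLength:
    """Optimum length from L∞ via the empirical log-linear relationship.

    ``lopt = 10 ** (1.0421 * log10(l_inf) - 0.2742)`` with interval bounds
    at 0.9 and 1.1 times ``lopt``.
    """
    if not l_inf > 0:
        raise ValueError("l_inf must be positive")
    lopt = 10.0 ** (1.0421 * np.log10(l_inf) - 0.2742)
    return OptimalLength(lopt=float(lopt), lo=0.9 * lopt, hi=1.1 * lopt)


def classify_fish(tl_cm: float, lm50: float, opt: OptimalLength) -> FishClass:
    """Classify one fish as mature / in-optimum-interval / mega-spawner.

    Mature is inclusive at ``lm50``; the optimum interval is closed; mega
    is strict beyond ``hi``, so a mega fish is mature but not "in
    interval" (assuming, as here, that ``hi > lm50``).
    """
    if tl_cm <= 0 or lm50 <= 0:
        raise ValueError("lengths must be positive")
    return FishClass(
        mature=tl_cm >= lm50,
        in_opt_interval=opt.lo <= tl_cm <= opt.hi,
        mega=tl_cm > opt.mega_threshold,
    )


def compute_indicators(
    ds: LengthDataset,
    lh: LifeHistory,
    opt: OptimalLength | None = None,
) -> pd.DataFrame:
    """Per-year indicator table: n, %mature, %optimum, %mega, mean/sd TL.

    Percentages are ``100 × count / n`` at full precision; mean and sd use
    the n−1 denominator convention of
    :func:`lenassess.core_data.summarize_by_year`.  Years registered as
    empty are omitted with a warning.  Output is ordered by year.
    """
    if len(ds) == 0:
        raise ValueError("compute_indicators: empty dataset")
    if opt is None:
        opt = compute_lopt(lh.l_inf)
    rows = []
    for year in ds.years:
        tl = ds.lengths(year)
        n = len(tl)
        if n == 0:
            logger.warning("year %d has no fish; omitted from indicators", year)
            continue
        rows.append({
            "year": year,
            "n": n,
            "pct_mature": 100.0 * np.count_nonzero(tl >= lh.lm50) / n,
            "pct_opt": 100.0 * np.count_nonzero((tl >= opt.lo) & (tl <= opt.hi)) / n,
            "pct_mega": 100.0 * np.count_nonzero(tl > opt.mega_threshold) / n,
            "mean_tl": float(np.mean(tl)),
            "sd_tl": float(np.std(tl, ddof=1)) if n > 1 else float("nan"),
        })
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def health_flags(
    row: pd.Series | dict,
    pct_mature_healthy: float = HEALTHY_PCT_MATURE,
    pct_opt_healthy: float = HEALTHY_PCT_OPT,
    pct_mega_healthy_lo: float = HEALTHY_PCT_MEGA_RANGE[0],
) -> HealthFlags:
    """Evaluate one indicator row against healthy-stock reference levels."""
    return HealthFlags(
        recruitment_overfishing=row["pct_mature"] < pct_mature_healthy,
        growth_overfishing=row["pct_opt"] < pct_opt_healthy,
        mega_spawner_deficit=row["pct_mega"] < pct_mega_healthy_lo,
    )
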