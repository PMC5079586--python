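"""Catch-curve mortality and generational turnover.

Ages are assigned to landed fish by inverting the von Bertalanffy growth
curve (an age–length key is not available for this fishery), a catch-at-age
frequency is built, and total mortality Z is estimated from the descending
limb with the Chapman–Robson survival estimator

    S = T / (n + T - 1)

where n is the number of fish on the limb and T the sum of their recoded
ages (ages minus the first limb age), together with the bias-corrected

    Z = -log(S) - (n - 1)(n - 2) / (n (T + 1)(n + T - 1)).

Only ages at or after the peak of the catch curve are used, so that the
estimate reflects age classes fully recruited to the gear.  The age
assignment depends on t0 and k, neither of which is identifiable from
length data alone; both are echoed in every estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_data import LengthDataset, LifeHistory

logger = logging.getLogger(__name__)


@dataclass
class AgeFrequency:
    """Catch-at-age counts with the descending limb marked out.

    ``recoded`` are limb ages minus the first limb age (so they start
    at 0), the form the Chapman–Robson estimator consumes.
    """

    ages: np.ndarray
    counts: np.ndarray
    peak_age: int
    limb_ages: np.ndarray
    recoded: np.ndarray
    n_capped: int = 0  # fish at or above L∞ mapped to tmax

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, int)
        self.counts = np.asarray(self.counts, int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.limb_ages[0] < self.peak_age:
            raise ValueError("descending limb must start at or after the peak")
        if self.recoded[0] != 0:
            raise ValueError("recoded ages must start at 0")

    @property
    def limb_counts(self) -> np.ndarray:
        idx = np.searchsorted(self.ages, self.limb_ages)
        return self.counts[idx]


@dataclass
class MortalityEstimate:
    """Chapman–Robson survival and bias-corrected total mortality.

    ``s_annual`` is a fraction (format ×100 for percent); ``z_total`` is
    the bias-corrected instantaneous rate, always ≤ −log(S).  ``config``
    echoes the age-assignment choices (t0, k, limb rule) the numbers
    depend on.
    """

    s_annual: float
    z_total: float
    se_s: float
    se_z: float
    n_used: int
    t_sum: float
    degenerate: bool = False
    config: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TurnoverEstimate:
    """Mean generational turnover time in years."""

    gt_years: float
    am: float
    tmax: float

    def __post_init__(self) -> None:
        if not (self.am <= self.gt_years <= self.tmax):
            raise ValueError("gt_years must lie in [am, tmax]")


def assign_age(tl_cm: float | np.ndarray, lh: LifeHistory) -> np.ndarray:
    """Integer age from length by inverse von Bertalanffy.

    ``a = t0 - log(1 - tl/L∞)/k`` floored to an integer and clipped to
    [0, tmax]; fish at or above L∞ (where the inversion is undefined) are
    capped at tmax.
    """
    tl = np.asarray(tl_cm, float)
    if np.any(tl <= 0):
        raise ValueError("lengths must be positive")
    tmax = lh.tmax if lh.tmax is not None else -np.log(0.01) / lh.m_nat
    with np.errstate(divide="ignore", invalid="ignore"):
        a = lh.t0 - np.log(1.0 - tl / lh.l_inf) / lh.k_growth
    a = np.where(tl >= lh.l_inf, tmax, a)
    return np.clip(np.floor(a), 0, np.floor(tmax)).astype(int)


def build_age_frequency(ds: LengthDataset, lh: LifeHistory,
                        limb_rule: str = "peak") -> AgeFrequency:
    """Catch-at-age table with the descending limb located.

    ``limb_rule`` is ``"peak"`` (limb starts at the modal age, the
    default) or ``"peak_plus_one"``.  Raises if the data collapse to a
    single age class, which has no descending limb.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    if limb_rule not in ("peak", "peak_plus_one"):
        raise ValueError(f"unknown limb rule: {limb_rule!r}")
    tl = ds.lengths()
    n_capped = int(np.count_nonzero(tl >= lh.l_inf))
    if n_capped:
        logger.warning("%d fish at or above L∞ capped at tmax", n_capped)
    age = assign_age(tl, lh)
    ages = np.arange(age.min(), age.max() + 1)
    counts = np.bincount(age - age.min(), minlength=len(ages))
    peak_age = int(ages[np.argmax(counts)])
    start = peak_age if limb_rule == "peak" else peak_age + 1
    limb_ages = ages[ages >= start]
    if len(limb_ages) < 2:
        raise ValueError("no descending limb: fewer than two age classes "
                         "at or after the peak")
    return AgeFrequency(ages=ages, counts=counts, peak_age=peak_age,
                        limb_ages=limb_ages, recoded=limb_ages - limb_ages[0],
                        n_capped=n_capped)


def chapman_robson(af: AgeFrequency, config: dict | None = None
                   ) -> MortalityEstimate:
    """Chapman–Robson survival with bias-corrected total mortality.

    With ``n`` fish on the descending limb and ``T`` the sum of their
    recoded ages: ``S = T/(n + T − 1)``;
    ``Z = −log(S) − (n−1)(n−2)/(n(T+1)(n+T−1))``.
    ``se_s = sqrt(S(S − (T−1)/(n+T−2)))`` (the estimator's exact variance)
    and ``se_z = (1−S)/sqrt(nS)``.  ``T = 0`` (every limb fish at the peak
    age) yields the degenerate S = 0 estimate, flagged rather than raised.
    """
    counts = af.limb_counts
    n = int(counts.sum())
    if len(af.limb_ages) < 2:
        raise ValueError("descending limb has fewer than 2 age classes")
    if n < 3:
        raise ValueError(f"descending limb has only {n} fish (need >= 3)")
    t_sum = float(np.sum(af.recoded * counts))
    s = t_sum / (n + t_sum - 1.0)
    if t_sum == 0:
        logger.warning("chapman_robson: T = 0, degenerate S = 0 estimate")
        return MortalityEstimate(s_annual=0.0, z_total=float("inf"),
                                 se_s=float("nan"), se_z=float("nan"),
                                 n_used=n, t_sum=t_sum, degenerate=True,
                                 config=config or {})
    z = -np.log(s) - (n - 1.0) * (n - 2.0) / (n * (t_sum + 1.0) * (n + t_sum - 1.0))
    var_s = s * (s - (t_sum - 1.0) / (n + t_sum - 2.0))
    se_s = float(np.sqrt(max(var_s, 0.0)))
    se_z = float((1.0 - s) / np.sqrt(n * s))
    return MortalityEstimate(s_annual=float(s), z_total=float(z),
                             se_s=se_s, se_z=se_z, n_used=n, t_sum=t_sum,
                             config=config or {})


def estimate_mortality(ds: LengthDataset, lh: LifeHistory,
                       limb_rule: str = "peak") -> MortalityEstimate:
    """Length records → ages → catch curve → Chapman–Robson, one call.

    The returned estimate echoes the age-assignment configuration
    (t0, k, tmax, limb rule) because Z is not identified without it.
    """
    af = build_age_frequency(ds, lh, limb_rule=limb_rule)
    cfg = {"t0": lh.t0, "k_growth": lh.k_growth, "tmax": lh.tmax,
           "limb_rule": limb_rule, "peak_age": af.peak_age,
           "n_capped": af.n_capped}
    return chapman_robson(af, config=cfg)


def generational_turnover(am: float, tmax: float) -> TurnoverEstimate:
    """Mean generational turnover: age at maturity plus half the
    remaining lifespan, ``GT = AM + (Tmax − AM)/2``.
    """
    if not 0 < am <= tmax:
        raise ValueError("require 0 < am <= tmax")
    return TurnoverEstimate(gt_years=am + (tmax - am) / 2.0, am=am, tmax=tmax)
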