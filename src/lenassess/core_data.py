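"""Domain types and I/O for per-fish landing records and life-history parameters.

The universal input of every analysis in this package is a flat table of
landed fish — one row per fish with the calendar year it was landed, a
free-text label for the dataset it came from (monitoring programme, thesis,
digitised figure, ...), and its total length in centimetres.  This module
provides the validated container for those records (:class:`LengthDataset`),
the life-history parameter block shared by all models (:class:`LifeHistory`),
and CSV readers/writers that never silently drop a row: every rejection is
counted and attributed to a rule in a :class:`ValidationReport`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Hard upper bound on a credible total length (cm).  Well above any grouper
#: on record; lengths beyond it are treated as data-entry errors.
DEFAULT_MAX_LENGTH_CM = 200.0

YEAR_MIN, YEAR_MAX = 1900, 2100

#: Default logical-field -> column-name mapping for landing CSVs.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "year": "year",
    "source": "source",
    "tl_cm": "tl_cm",
}


@dataclass(frozen=True)
class LengthRecord:
    """One landed fish: year, dataset label, and total length in cm."""

    year: int
    source: str
    tl_cm: float

    def __post_init__(self) -> None:
        if not self.tl_cm > 0:
            raise ValueError(f"tl_cm must be positive, got {self.tl_cm}")
        if not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValueError(f"year {self.year} outside [{YEAR_MIN}, {YEAR_MAX}]")


@dataclass
class LengthDataset:
    """Ordered collection of landing records with a provenance note.

    Internally a pandas DataFrame with columns ``year``, ``source``,
    ``tl_cm`` in original row order.  Years with zero fish are representable
    through :meth:`with_empty_years` / the ``empty_years`` attribute and are
    reported, never dropped, by downstream summaries.
    """

    df: pd.DataFrame
    provenance: str = ""
    empty_years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        required = ["year", "source", "tl_cm"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"LengthDataset missing columns: {missing}")
        self.df = self.df[required].reset_index(drop=True)
        self.df["year"] = self.df["year"].astype(int)
        self.df["tl_cm"] = self.df["tl_cm"].astype(float)
        self.df["source"] = self.df["source"].astype(str)

    @classmethod
    def from_records(
        cls, records: Iterable[LengthRecord], provenance: str = ""
    ) -> "LengthDataset":
        rows = [(r.year, r.source, r.tl_cm) for r in records]
        df = pd.DataFrame(rows, columns=["year", "source", "tl_cm"])
        return cls(df, provenance=provenance)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[LengthRecord]:
        for row in self.df.itertuples(index=False):
            yield LengthRecord(int(row.year), str(row.source), float(row.tl_cm))

    @property
    def years(self) -> list[int]:
        """Distinct years present (including registered empty years), sorted."""
        ys = set(self.df["year"].tolist()) | set(self.empty_years)
        return sorted(ys)

    def lengths(self, year: int | None = None) -> np.ndarray:
        """Total lengths (cm), optionally restricted to one year."""
        if year is None:
            return self.df["tl_cm"].to_numpy()
        return self.df.loc[self.df["year"] == year, "tl_cm"].to_numpy()

    def subset_year(self, year: int) -> "LengthDataset":
        sub = self.df[self.df["year"] == year]
        return LengthDataset(sub.copy(), provenance=f"{self.provenance} [year={year}]")

    def with_empty_years(self, years: Iterable[int]) -> "LengthDataset":
        return replace(self, empty_years=tuple(sorted(set(years))))


@dataclass
class ValidationReport:
    """Bookkeeping for a read: rows read, kept, rejected, and why."""

    n_read: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.n_rejected += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    def check(self) -> None:
        if self.n_read != self.n_kept + self.n_rejected:
            raise AssertionError("ValidationReport counts are inconsistent")


@dataclass
class LifeHistory:
    """Biological parameters shared by all length-based models.

    Growth follows the von Bertalanffy curve
    ``L(a) = l_inf * (1 - exp(-k_growth * (a - t0)))``.  Exactly two of
    ``m_nat``, ``k_growth``, ``m_over_k`` may be supplied and the third is
    derived; if all three are supplied they must be consistent to 1e-9
    (relative).  The maturity ogive is a logistic anchored at ``lm50`` and
    ``lm95``; when ``lm95`` is omitted it defaults to ``1.1 * lm50``.

    Parameters
    ----------
    l_inf
        Asymptotic length L∞ (cm).
    cv_linf
        Coefficient of variation of L∞ among individuals (dimensionless).
    m_nat
        Instantaneous natural mortality M (1/yr).
    k_growth
        Brody growth coefficient k (1/yr).
    m_over_k
        Ratio M/k — the key input of length-based per-recruit methods.
    t0
        Theoretical age at zero length (yr).
    lm50, lm95
        Lengths at 50% and 95% maturity (cm).
    fec_b
        Exponent of the fecundity–length power law (eggs ∝ length**fec_b);
        3 corresponds to fecundity proportional to weight.
    am
        Female age at maturity (yr).
    tmax
        Maximum age (yr); the oldest age class carried by the models.
    max_len
        Reported maximum observed length (cm), informational.
    """

    l_inf: float
    lm50: float
    m_nat: float | None = None
    k_growth: float | None = None
    m_over_k: float | None = None
    cv_linf: float = 0.10
    t0: float = 0.0
    lm95: float | None = None
    fec_b: float = 3.0
    am: float | None = None
    tmax: float | None = None
    max_len: float | None = None

    def __post_init__(self) -> None:
        if not self.l_inf > 0:
            raise ValueError("l_inf must be positive")
        given = [self.m_nat is not None, self.k_growth is not None,
                 self.m_over_k is not None]
        if sum(given) < 2:
            raise ValueError(
                "need at least two of m_nat, k_growth, m_over_k")
        if self.m_nat is None:
            self.m_nat = self.m_over_k * self.k_growth
        elif self.k_growth is None:
            self.k_growth = self.m_nat / self.m_over_k
        elif self.m_over_k is None:
            self.m_over_k = self.m_nat / self.k_growth
        else:
            if not math.isclose(self.m_over_k, self.m_nat / self.k_growth,
                                rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(
                    "m_over_k inconsistent with m_nat / k_growth")
        if self.m_nat <= 0 or self.k_growth <= 0:
            raise ValueError("m_nat and k_growth must be positive")
        if self.lm95 is None:
            self.lm95 = 1.1 * self.lm50
        if not (0 < self.lm50 < self.lm95 < self.l_inf):
            raise ValueError("require 0 < lm50 < lm95 < l_inf")
        if self.cv_linf < 0:
            raise ValueError("cv_linf must be nonnegative")
        if self.am is not None and self.tmax is not None:
            if not (0 < self.am < self.tmax):
                raise ValueError("require 0 < am < tmax")

    def mean_length_at_age(self, age: np.ndarray | float) -> np.ndarray | float:
        """von Bertalanffy mean length at age (cm), floored at 0."""
        return self.l_inf * np.maximum(
            0.0, 1.0 - np.exp(-self.k_growth * (np.asarray(age, float) - self.t0))
        )


def read_length_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    max_length_cm: float = DEFAULT_MAX_LENGTH_CM,
    provenance: str | None = None,
) -> tuple[LengthDataset, ValidationReport]:
    """Read per-fish landing records from a delimited text file.

    ``column_map`` maps the logical fields ``year``, ``source``, ``tl_cm``
    to the column names actually present in the file (defaults assume the
    logical names).  Rows failing a record invariant (non-positive or
    implausibly large length, unparseable number, year out of range) are
    rejected individually and tallied in the returned
    :class:`ValidationReport`; a missing file or missing mapped column is
    fatal.  Surviving rows keep their input order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for logical, col in cmap.items():
        if col not in raw.columns:
            raise ValueError(f"mapped column {col!r} (for {logical!r}) "
                             f"not in header of {path}")

    report = ValidationReport(n_read=len(raw))
    years = pd.to_numeric(raw[cmap["year"]], errors="coerce")
    tls = pd.to_numeric(raw[cmap["tl_cm"]], errors="coerce")
    sources = raw[cmap["source"]].astype(str)

    keep = np.ones(len(raw), dtype=bool)
    for i in range(len(raw)):
        if np.isnan(years.iloc[i]):
            report.reject("unparseable year")
        elif not (YEAR_MIN <= years.iloc[i] <= YEAR_MAX):
            report.reject("year out of range")
        elif np.isnan(tls.iloc[i]):
            report.reject("unparseable length")
        elif tls.iloc[i] <= 0:
            report.reject("nonpositive length")
        elif tls.iloc[i] > max_length_cm:
            report.reject("length above hard cap")
        else:
            continue
        keep[i] = False

    df = pd.DataFrame({
        "year": years[keep].astype(int).to_numpy(),
        "source": sources[keep].to_numpy(),
        "tl_cm": tls[keep].to_numpy(),
    })
    report.n_kept = len(df)
    report.check()
    if report.n_rejected:
        logger.warning("read %s: rejected %d of %d rows (%s)",
                       path, report.n_rejected, report.n_read, report.reasons)
    ds = LengthDataset(df, provenance=provenance or str(path))
    return ds, report


def write_length_records(ds: LengthDataset, path: str | Path,
                         delimiter: str = ",") -> None:
    """Write a dataset back to CSV with the canonical column names.

    Round-trips with :func:`read_length_records`: order and full numeric
    precision are preserved.
    """
    out = ds.df.copy()
    # repr-precision floats so a re-read reproduces values exactly
    out["tl_cm"] = out["tl_cm"].map(repr)
    out.to_csv(path, sep=delimiter, index=False)


def summarize_by_year(ds: LengthDataset) -> pd.DataFrame:
    """Per-year sample size, mean and sd of total length.

    The sd uses the n−1 denominator; a year with a single fish reports
    ``NaN`` (undefined), never 0.  Years registered as empty appear with
    ``n = 0``.  An empty dataset yields an empty table with a warning.
    """
    if len(ds) == 0 and not ds.empty_years:
        logger.warning("summarize_by_year: empty dataset")
        return pd.DataFrame(columns=["year", "n", "mean_tl", "sd_tl"])
    rows = []
    by_year = {int(y): g["tl_cm"].to_numpy() for y, g in ds.df.groupby("year")}
    for year in ds.years:
        tl = by_year.get(year, np.array([]))
        n = len(tl)
        mean = float(np.mean(tl)) if n else float("nan")
        sd = float(np.std(tl, ddof=1)) if n > 1 else float("nan")
        rows.append((year, n, mean, sd))
    out = pd.DataFrame(rows, columns=["year", "n", "mean_tl", "sd_tl"])
    out["n"] = out["n"].astype(int)
    return out
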