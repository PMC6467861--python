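"""Isotope value arithmetic, group summaries, and source pooling.

Stable-isotope abundances are expressed in delta notation: the per-mil
deviation of a sample's heavy/light isotope ratio from an international
standard, ``delta = (R_sample / R_standard - 1) * 1000``.  Consumers and
diet items each carry a (d13C, d15N) pair in per mil (permil, ``‰``).

Diet items whose carbon and nitrogen signatures are statistically
indistinguishable cannot be separated by a two-isotope mixing model, so
they are screened with Welch t-tests and, when non-distinct on both
isotopes, pooled into a single grouped source (e.g. epigeous fungi +
phloem).  Pooling works on summary moments and is exactly equivalent to
concatenating the underlying raw samples.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("nichemix")

#: Plausible delta ranges for consumer/diet tissue; values outside raise a
#: warning (not an error) because extreme but genuine values exist.
D13C_RANGE = (-40.0, 0.0)
D15N_RANGE = (-10.0, 20.0)

#: Instrumental precision of the isotope-ratio measurement, recorded as
#: metadata only (not propagated into any likelihood).
MEASUREMENT_PRECISION = {"d13c": 0.10, "d15n": 0.2}

VALID_SEASONS = {"summer", "fall"}
VALID_AREAS = {"treatment", "control", "none"}
VALID_SEXES = {"M", "F", "unknown"}
VALID_TISSUES = {"dorsal_hair", "tail_hair", "diet_item"}


class IsotopeRangeWarning(UserWarning):
    """A delta value fell outside the plausible biological range."""


@dataclass(frozen=True)
class IsotopePair:
    """One individual's (d13C, d15N) measurement in permil."""

    d13c: float
    d15n: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d13c) and math.isfinite(self.d15n)):
            raise ValueError(f"isotope values must be finite, got {self}")
        if not (D13C_RANGE[0] <= self.d13c <= D13C_RANGE[1]):
            warnings.warn(
                f"d13c={self.d13c} outside plausible range {D13C_RANGE}",
                IsotopeRangeWarning,
                stacklevel=2,
            )
        if not (D15N_RANGE[0] <= self.d15n <= D15N_RANGE[1]):
            warnings.warn(
                f"d15n={self.d15n} outside plausible range {D15N_RANGE}",
                IsotopeRangeWarning,
                stacklevel=2,
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.d13c, self.d15n], dtype=float)


@dataclass(frozen=True)
class SampleRecord:
    """A labelled isotope sample: one hair or diet-item measurement.

    Fall diet is recorded by dorsal or tail hair collected December-May
    (hair grown in fall); summer diet by dorsal hair collected
    August-September.  Tail hair is grown only in fall, so a summer tail
    record violates the molt-based assignment rule.
    """

    id: str
    group: str
    site: str
    season: str
    year: int
    area: str
    sex: str
    tissue: str
    values: IsotopePair

    def __post_init__(self) -> None:
        if self.season not in VALID_SEASONS:
            raise ValueError(f"season must be one of {VALID_SEASONS}, got {self.season!r}")
        if self.area not in VALID_AREAS:
            raise ValueError(f"area must be one of {VALID_AREAS}, got {self.area!r}")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if self.tissue not in VALID_TISSUES:
            raise ValueError(f"tissue must be one of {VALID_TISSUES}, got {self.tissue!r}")
        if self.tissue == "tail_hair" and self.season != "fall":
            raise ValueError("tail hair is grown only in fall; summer tail record is invalid")


@dataclass(frozen=True)
class SourceDistribution:
    """Per-diet-item isotope distribution: mean, SD and n per isotope.

    This is the mixing-model endmember.  ``sd`` components must be
    non-negative and ``n >= 2`` so that the sample SD is defined.
    """

    name: str
    mean: IsotopePair
    sd: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd):
            raise ValueError(f"source {self.name!r}: sd components must be >= 0, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"source {self.name!r}: n must be >= 2, got {self.n}")

    @property
    def mean_array(self) -> np.ndarray:
        return self.mean.as_array()

    @property
    def sd_array(self) -> np.ndarray:
        return np.array(self.sd, dtype=float)


# ---------------------------------------------------------------------------
# delta notation
# ---------------------------------------------------------------------------

def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """Convert an isotope abundance ratio to permil delta notation.

    ``delta = (r_sample / r_standard - 1) * 1000``.

    Parameters
    ----------
    r_sample : heavy/light isotope ratio of the sample (>= 0).
    r_standard : heavy/light ratio of the reference standard (> 0).
    """
    if r_standard <= 0:
        raise ValueError(f"standard ratio must be > 0, got {r_standard}")
    if r_sample < 0:
        raise ValueError(f"sample ratio must be >= 0, got {r_sample}")
    return (r_sample / r_standard - 1.0) * 1000.0


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def summarize_group(
    records: Sequence[SampleRecord],
    name: str | None = None,
    allow_mixed_tissue: bool = False,
) -> SourceDistribution:
    """Summarise a group of samples into a mean/SD/n source distribution.

    Uses the sample (n-1 denominator) standard deviation; values are kept
    at full precision here and rounded only at report time.

    Raises
    ------
    ValueError
        If fewer than two records (SD undefined), or if the records mix
        tissue types and ``allow_mixed_tissue`` is not set.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need >= 2 records for a sample SD")
    tissues = {r.tissue for r in records}
    if len(tissues) > 1 and not allow_mixed_tissue:
        raise ValueError(
            f"records mix tissue types {sorted(tissues)}; pass allow_mixed_tissue=True to override"
        )
    x = np.array([[r.values.d13c, r.values.d15n] for r in records], dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return SourceDistribution(
        name=name if name is not None else records[0].group,
        mean=IsotopePair(float(mean[0]), float(mean[1])),
        sd=(float(sd[0]), float(sd[1])),
        n=len(records),
    )


# ---------------------------------------------------------------------------
# distinctness screening
# ---------------------------------------------------------------------------

def welch_t_test(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test; Welch (unequal variances) by default.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p-value.  With ``equal_var=True`` the pooled-variance
    variant is used instead.  When both groups have zero variance and equal
    means the test is degenerate and ``(0, n-2, 1.0)`` is returned by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            logger.warning("welch_t_test: zero variance in both groups with equal means")
            return 0.0, float(a.size + b.size - 2), 1.0
        logger.warning("welch_t_test: zero variance in both groups with unequal means")
        return math.inf if a.mean() > b.mean() else -math.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def sources_distinct(
    a_samples: np.ndarray, b_samples: np.ndarray, alpha: float = 0.05
) -> bool:
    """Are two diet items isotopically distinct on at least one isotope?

    ``a_samples``/``b_samples`` are (n, 2) arrays of (d13C, d15N).  Items
    are considered distinct if the Welch test rejects at ``alpha`` on
    either isotope; only items non-distinct on BOTH are candidates for
    pooling.
    """
    a_samples = np.atleast_2d(np.asarray(a_samples, dtype=float))
    b_samples = np.atleast_2d(np.asarray(b_samples, dtype=float))
    for j in range(2):
        _, _, p = welch_t_test(a_samples[:, j], b_samples[:, j])
        if p <= alpha:
            return True
    return False


# ---------------------------------------------------------------------------
# source pooling
# ---------------------------------------------------------------------------

def _pool_moments(
    mu_a: float, sd_a: float, n_a: int, mu_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Pooled mean and sample SD equivalent to concatenating raw samples."""
    n = n_a + n_b
    mean = (n_a * mu_a + n_b * mu_b) / n
    ss = (
        (n_a - 1) * sd_a**2
        + (n_b - 1) * sd_b**2
        + n_a * n_b * (mu_a - mu_b) ** 2 / n
    )
    return mean, math.sqrt(ss / (n - 1))


def pool_sources(
    a: SourceDistribution,
    b: SourceDistribution,
    name: str | None = None,
    distinct: bool | None = None,
    force: bool = False,
) -> SourceDistribution:
    """Pool two source distributions into one grouped diet source.

    The pooled moments are exactly those of the concatenated raw samples
    (per isotope): mean is the n-weighted convex combination of the input
    means, and the sample variance combines within-group and between-group
    sums of squares.

    Parameters
    ----------
    distinct : pass the result of a distinctness screen; pooling sources
        known to be distinct is refused unless ``force`` is given.
    """
    if distinct and not force:
        raise ValueError(
            f"refusing to pool isotopically distinct sources {a.name!r} and {b.name!r}; "
            "pass force=True to override"
        )
    m13, s13 = _pool_moments(a.mean.d13c, a.sd[0], a.n, b.mean.d13c, b.sd[0], b.n)
    m15, s15 = _pool_moments(a.mean.d15n, a.sd[1], a.n, b.mean.d15n, b.sd[1], b.n)
    return SourceDistribution(
        name=name if name is not None else f"{a.name}+{b.name}",
        mean=IsotopePair(m13, m15),
        sd=(s13, s15),
        n=a.n + b.n,
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_sources_csv(path) -> list[SourceDistribution]:
    """Read a wide-form sources table: item,n,d13c_mean,d13c_sd,d15n_mean,d15n_sd."""
    df = pd.read_csv(path, comment="#")
    required = {"item", "n", "d13c_mean", "d13c_sd", "d15n_mean", "d15n_sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sources CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SourceDistribution(
                name=str(row.item),
                mean=IsotopePair(float(row.d13c_mean), float(row.d15n_mean)),
                sd=(float(row.d13c_sd), float(row.d15n_sd)),
                n=int(row.n),
            )
        )
    return out


def write_sources_csv(sources: Iterable[SourceDistribution], path) -> None:
    rows = [
        {
            "item": s.name,
            "n": s.n,
            "d13c_mean": s.mean.d13c,
            "d13c_sd": s.sd[0],
            "d15n_mean": s.mean.d15n,
            "d15n_sd": s.sd[1],
        }
        for s in sources
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


CONSUMER_COLUMNS = ["id", "group", "site", "season", "year", "area", "sex", "d13c", "d15n"]


def read_consumers_csv(path) -> pd.DataFrame:
    """Read a consumers table (id,group,site,season,year,area,sex,d13c,d15n)."""
    df = pd.read_csv(path, comment="#")
    missing = set(CONSUMER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"consumers CSV missing columns: {sorted(missing)}")
    bad_season = set(df["season"].unique()) - VALID_SEASONS
    if bad_season:
        raise ValueError(f"consumers CSV contains invalid seasons: {sorted(bad_season)}")
    return df


def consumer_matrix(df: pd.DataFrame) -> np.ndarray:
    """Extract the (n, 2) consumer isotope matrix from a consumers table."""
    return df[["d13c", "d15n"]].to_numpy(dtype=float)
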