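"""Removal-efficacy statistics: camera counts and Mann-Whitney tests.

Camera counting rule: animals on a transect are unmarked and do not hold
exclusive territories, so every single-animal photograph within one
(transect, hour) window is assumed to show the same individual and
counts once; an image with two animals in frame counts two.

Treatment vs. control comparisons use the Mann-Whitney U test in the
first-sample convention with half-credit for ties,
``W = sum_ij [1(x_i > y_j) + 0.5 * 1(x_i = y_j)]``, which can take
fractional values under ties.  P-values are exact (full enumeration of
labelings) for tie-free small samples and tie-corrected normal with
continuity correction otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("nichemix")

EXACT_MAX_N = 20  # total n above which exact enumeration is not attempted


@dataclass(frozen=True)
class CameraEvent:
    """One triggered photograph: transect, area, hour stamp, animals in frame."""

    transect: str
    area: str
    hour: int  # hours since transect start (any consistent integer clock)
    squirrels_in_frame: int

    def __post_init__(self) -> None:
        if self.squirrels_in_frame not in (1, 2):
            raise ValueError(
                f"squirrels_in_frame must be 1 or 2, got {self.squirrels_in_frame}"
            )


@dataclass(frozen=True)
class TransectCount:
    """One survey's feeding-sign (or photo) count on a transect."""

    transect: str
    area: str
    date: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


def unique_photograph_count(events: list[CameraEvent], transects: list[str] | None = None) -> dict[str, int]:
    """Per-transect unique-animal totals under the hourly counting rule.

    Any number of single-animal images within one (transect, hour) adds 1;
    each two-animal image adds 2.  ``transects`` may list transects that
    should appear in the output even with zero events.
    """
    totals: dict[str, int] = {t: 0 for t in (transects or [])}
    single_hours: set[tuple[str, int]] = set()
    for ev in events:
        totals.setdefault(ev.transect, 0)
        if ev.squirrels_in_frame == 2:
            totals[ev.transect] += 2
        else:
            key = (ev.transect, ev.hour)
            if key not in single_hours:
                single_hours.add(key)
                totals[ev.transect] += 1
    return totals


def per_transect_mean(totals: list[float] | np.ndarray, n_transects: int | None = None) -> tuple[float, float]:
    """Mean and sample SD of per-transect totals, zero transects included.

    If ``n_transects`` exceeds the number of totals given, the remainder
    are treated as zero-count transects.
    """
    totals = list(np.asarray(totals, dtype=float))
    if n_transects is None:
        n_transects = len(totals)
    if n_transects < 1:
        raise ValueError("need n_transects >= 1")
    if n_transects < len(totals):
        raise ValueError("n_transects smaller than the number of totals supplied")
    x = np.array(totals + [0.0] * (n_transects - len(totals)))
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), sd


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """First-sample U with half-credit ties (fractional under ties)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(
    x, y, method: str = "auto"
) -> tuple[float, float, str]:
    """Mann-Whitney U test of two count samples.

    Returns ``(W, p, method_used)`` with W in the first-sample convention
    (see module docstring; the swap identity ``W + W' = n_x n_y`` holds
    exactly, ties included).

    method : {'auto', 'exact', 'normal'}
        'exact' enumerates the null distribution of U over all
        ``C(n_x+n_y, n_x)`` labelings (tie-free data, total n <= 20 only;
        with ties it falls back to 'normal' with a warning).  'normal'
        uses the tie-corrected Gaussian approximation with continuity
        correction.  'auto' picks 'exact' when feasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs n >= 1")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    W = _u_statistic(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    n_tot = x.size + y.size

    want_exact = method == "exact" or (method == "auto" and not has_ties and n_tot <= EXACT_MAX_N)
    if want_exact and (has_ties or n_tot > EXACT_MAX_N):
        warnings.warn(
            "exact Mann-Whitney p unavailable (ties or n too large); "
            "falling back to tie-corrected normal approximation",
            UserWarning,
            stacklevel=2,
        )
        want_exact = False

    if want_exact:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return W, float(res.pvalue), "exact"

    nx, ny = x.size, y.size
    mu = nx * ny / 2.0
    allv = np.concatenate([x, y])
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n_tot * (n_tot - 1.0))
    var = nx * ny / 12.0 * (n_tot + 1.0 - tie_term)
    if var == 0.0:  # all observations identical
        return W, 1.0, "normal"
    z = (abs(W - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return W, float(min(p, 1.0)), "normal"


def removal_tests(transects_df: pd.DataFrame) -> pd.DataFrame:
    """Treatment-vs-control Mann-Whitney comparisons from a transects table.

    ``transects_df`` needs columns transect, area, date, count.  The
    number of transects is taken from the data, never assumed.  One test
    row is produced per survey date plus an all-dates-total comparison.
    """
    required = {"transect", "area", "date", "count"}
    missing = required - set(transects_df.columns)
    if missing:
        raise ValueError(f"transects table missing columns: {sorted(missing)}")
    rows = []

    def one_test(label: str, sub: pd.DataFrame) -> None:
        t = sub[sub["area"] == "treatment"]["count"].to_numpy()
        c = sub[sub["area"] == "control"]["count"].to_numpy()
        if t.size == 0 or c.size == 0:
            return
        W, p, used = mann_whitney_u(t, c)
        rows.append(
            {"comparison": label, "W": W, "p": p, "method": used,
             "n_treatment": t.size, "n_control": c.size}
        )

    totals = transects_df.groupby(["transect", "area"], as_index=False)["count"].sum()
    one_test("total", totals)
    for date, sub in transects_df.groupby("date"):
        one_test(str(date), sub)
    return pd.DataFrame(rows)


def read_transects_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"transect", "area", "date", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"transects CSV missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("counts must be >= 0")
    return df


def read_camera_events_csv(path) -> list[CameraEvent]:
    df = pd.read_csv(path, comment="#")
    missing = {"transect", "area", "hour", "squirrels_in_frame"} - set(df.columns)
    if missing:
        raise ValueError(f"camera events CSV missing columns: {sorted(missing)}")
    return [
        CameraEvent(str(r.transect), str(r.area), int(r.hour), int(r.squirrels_in_frame))
        for r in df.itertuples(index=False)
    ]
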