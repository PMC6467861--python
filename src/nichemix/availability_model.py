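"""Carbon-availability index: z-scored food production regressed on d13C.

Annual conifer-seed and mushroom production is standardised against a
long-term baseline (default 21 years, 1994-2014): for each study year,
``z = (x - mean_baseline) / sd_baseline``.  Individual consumer d13C is
then modelled by ordinary least squares on the two availability z-scores
plus categorical covariates (season, removal group, area, sex, and a
group x area interaction), and the model is reduced by backward
elimination with AIC selection.

Factor coding (recorded in outputs): season fall=0/summer=1, group
before=0/after=1, area control=0/treatment=1, sex F=0/M=1.  The AIC
convention counts the residual variance as a parameter: for a model with
``k`` regression coefficients (intercept included), ``K = k + 1`` and
``AIC = -2 logL + 2K`` with the Gaussian log-likelihood evaluated at the
MLE variance RSS/n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("nichemix")

PROTECTED_TERMS = ("seeds_z", "mushrooms_z")
INTERACTION = "group:area"
#: Covariate declaration order; used for elimination tie-breaking.
TERM_ORDER = ("seeds_z", "mushrooms_z", "season", "group", "area", "sex", INTERACTION)

FACTOR_CODING = {
    "season": {"fall": 0, "summer": 1},
    "group": {"before": 0, "after": 1},
    "area": {"control": 0, "treatment": 1},
    "sex": {"F": 0, "M": 1},
}


@dataclass(frozen=True)
class ScaledAvailability:
    """One study year's production expressed as baseline z-scores."""

    year: int
    seeds_z: float
    mushrooms_z: float


@dataclass
class ModelFit:
    """An OLS fit in Table-4/5 shape: terms, estimates, and AIC."""

    terms: list[str]  # regression terms excluding the intercept
    params: pd.Series  # coefficients including 'Intercept'
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    resid_sd: float
    n: int
    k_params: int  # coefficients + 1 for the residual variance
    aic: float
    llf: float

    def model_label(self) -> str:
        short = {"seeds_z": "c", "mushrooms_z": "m", "season": "s", "group": "g",
                 "area": "a", "sex": "sx", INTERACTION: "(g*a)"}
        return " + ".join(short.get(t, t) for t in self.terms)


def read_production_csv(path) -> pd.DataFrame:
    """Read production.csv (year,seeds_per_m2,mushrooms_kg_ha)."""
    df = pd.read_csv(path, comment="#")
    missing = {"year", "seeds_per_m2", "mushrooms_kg_ha"} - set(df.columns)
    if missing:
        raise ValueError(f"production CSV missing columns: {sorted(missing)}")
    if (df[["seeds_per_m2", "mushrooms_kg_ha"]] < 0).any().any():
        raise ValueError("production values must be >= 0")
    return df


def scale_availability(
    series: pd.DataFrame,
    baseline_years: tuple[int, int],
    study_years: list[int],
) -> list[ScaledAvailability]:
    """Z-score each study year's production against the baseline span.

    The mean and sample SD come from the full baseline period (not the
    study-year subset).  Zero baseline SD for either resource is an error.
    """
    lo, hi = baseline_years
    base = series[(series["year"] >= lo) & (series["year"] <= hi)]
    if len(base) < 2:
        raise ValueError(f"baseline span {baseline_years} covers < 2 years of data")
    missing = set(study_years) - set(series["year"])
    if missing:
        raise ValueError(f"study years missing from series: {sorted(missing)}")
    out = []
    stats_ = {}
    for col in ("seeds_per_m2", "mushrooms_kg_ha"):
        mu = base[col].mean()
        sd = base[col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero baseline SD for {col}; z-scores undefined")
        stats_[col] = (mu, sd)
    by_year = series.set_index("year")
    for y in study_years:
        row = by_year.loc[y]
        out.append(
            ScaledAvailability(
                year=int(y),
                seeds_z=float((row["seeds_per_m2"] - stats_["seeds_per_m2"][0]) / stats_["seeds_per_m2"][1]),
                mushrooms_z=float(
                    (row["mushrooms_kg_ha"] - stats_["mushrooms_kg_ha"][0]) / stats_["mushrooms_kg_ha"][1]
                ),
            )
        )
    return out


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p).

    Degenerate inputs are guarded: all observations identical across all
    groups gives F = 0, p = 1; zero within-group variance with unequal
    means gives p ~ 0 with a logged warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 groups each with n >= 1")
    N = sum(g.size for g in groups)
    g = len(groups)
    if N <= g:
        raise ValueError("total n must exceed the number of groups")
    df_b, df_w = g - 1, N - g
    allvals = np.concatenate(groups)
    within_ss = sum(float(np.sum((x - x.mean()) ** 2)) for x in groups)
    if within_ss == 0.0:
        if allvals.var() == 0.0:
            return 0.0, df_b, df_w, 1.0
        logger.warning("one_way_anova: zero within-group variance with unequal means")
        return np.inf, df_b, df_w, 0.0
    F, p = stats.f_oneway(*groups)
    return float(F), df_b, df_w, float(p)


# ---------------------------------------------------------------------------
# OLS and backward elimination
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Design matrix (with intercept) for numerically coded covariates.

    The interaction column is the product of its parent columns; factors
    must already be 0/1 coded per ``FACTOR_CODING``.
    """
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    for t in terms:
        if t == INTERACTION:
            X[t] = df["group"].astype(float) * df["area"].astype(float)
        else:
            X[t] = df[t].astype(float)
    return X


def fit_ols(df: pd.DataFrame, terms: list[str], response: str = "d13c") -> ModelFit:
    """Least-squares fit of d13C on the given terms.

    Coefficient SEs come from sigma-hat^2 (X'X)^-1 with sigma-hat^2 =
    RSS/(n-k); the AIC uses the Gaussian log-likelihood at the MLE
    variance RSS/n and counts the residual variance in K.
    """
    y = df[response].to_numpy(dtype=float)
    X = build_design(df, terms)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > number of coefficients ({n} <= {k})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        # name the aliased columns: those whose removal does not drop rank
        aliased = [c for c in X.columns if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    k_params = k + 1  # + residual variance
    aic = -2.0 * float(res.llf) + 2.0 * k_params
    return ModelFit(
        terms=list(terms),
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        resid_sd=float(np.sqrt(rss / (n - k))),
        n=n,
        k_params=k_params,
        aic=aic,
        llf=float(res.llf),
    )


def _eligible_terms(terms: list[str], protected: tuple[str, ...]) -> list[str]:
    """Droppable terms: non-protected, and parents of a still-present
    interaction are not eligible before the interaction itself."""
    eligible = [t for t in terms if t not in protected]
    if INTERACTION in terms:  # hierarchy: interaction must go before its parents
        eligible = [t for t in eligible if t not in ("group", "area")]
    return eligible


def backward_eliminate(
    df: pd.DataFrame,
    full_terms: list[str] | None = None,
    protected: tuple[str, ...] = PROTECTED_TERMS,
    alpha: float = 0.05,
    response: str = "d13c",
) -> tuple[list[ModelFit], ModelFit]:
    """Backward elimination from the full model, final model by AIC.

    At each step the highest-p non-protected term with p > alpha is
    dropped (the group x area interaction is eligible before its parents,
    never the reverse; at tied p-values the term later in declaration
    order goes first).  The path stops when every remaining non-protected
    term is significant or only protected terms remain; the final model is
    the minimum-AIC fit along the visited path.
    """
    if full_terms is None:
        full_terms = list(TERM_ORDER)
    terms = list(full_terms)
    path = [fit_ols(df, terms, response=response)]
    while True:
        fit = path[-1]
        eligible = _eligible_terms(fit.terms, protected)
        if not eligible:
            break
        pvals = {t: float(fit.pvalues[t]) for t in eligible}
        worst_p = max(pvals.values())
        if worst_p <= alpha:
            break
        # tie-break: later declaration order drops first
        candidates = [t for t, p in pvals.items() if p == worst_p]
        drop = max(candidates, key=lambda t: TERM_ORDER.index(t) if t in TERM_ORDER else -1)
        terms = [t for t in fit.terms if t != drop]
        path.append(fit_ols(df, terms, response=response))
    final = min(path, key=lambda f: f.aic)
    return path, final


def model_path_table(path: list[ModelFit]) -> pd.DataFrame:
    """Candidate-model table: model, K, AIC, dAIC, Akaike weight."""
    df = pd.DataFrame(
        {
            "model": [f.model_label() for f in path],
            "K": [f.k_params for f in path],
            "AIC": [f.aic for f in path],
        }
    ).sort_values("AIC", ignore_index=True)
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    w = np.exp(-0.5 * df["dAIC"].to_numpy())
    df["weight"] = w / w.sum()
    return df


def final_fit_table(fit: ModelFit) -> pd.DataFrame:
    """Final-model coefficient table: term, estimate, se, t, p."""
    return pd.DataFrame(
        {
            "term": list(fit.params.index),
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
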