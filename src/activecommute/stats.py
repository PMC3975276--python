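"""Comparative statistics for the travel-mode analysis.

One-way ANOVA group comparisons, paired weekday/weekend t-tests, adjusted
linear (OLS) models of weekday activity on travel mode, percent-difference
summaries, and the day-level walking-day vs car-day comparison.

Normality is assumed throughout; all p-values are two-sided and no
multiple-testing correction is applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "GroupStats",
    "GroupComparison",
    "TermEstimate",
    "AdjustedModel",
    "ADJUSTED_MODEL_TERMS",
    "compare_groups",
    "paired_weekday_weekend",
    "fit_adjusted_model",
    "percent_difference",
    "day_level_comparison",
]


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA over named groups."""

    groups: dict[str, GroupStats]
    f: float
    p: float


@dataclass(frozen=True)
class TermEstimate:
    term: str
    coef: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class AdjustedModel:
    """OLS fit of one outcome on travel mode plus confounders."""

    outcome: str
    terms: tuple[TermEstimate, ...]
    n: int
    r_squared: float

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


def compare_groups(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA across two or more groups of continuous values."""
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = {}
    for name, vals in values_by_group.items():
        a = np.asarray(list(vals), dtype=float)
        a = a[~np.isnan(a)]
        if len(a) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        arrays[name] = a
    f, p = sps.f_oneway(*arrays.values())
    if np.isnan(f):  # all groups identical and constant
        f, p = 0.0, 1.0
    groups = {
        name: GroupStats(n=len(a), mean=float(a.mean()), sd=float(a.std(ddof=1)))
        for name, a in arrays.items()
    }
    return GroupComparison(groups=groups, f=float(f), p=float(p))


def paired_weekday_weekend(
    weekday: Sequence[float], weekend: Sequence[float]
) -> tuple[float, float]:
    """Paired t-test on per-participant weekday vs weekend values.

    Inputs are aligned per participant. Zero-variance differences are a
    degenerate limit: a constant non-zero shift returns (±inf, 0.0) with a
    warning instead of crashing; identical pairs return (0.0, 1.0).
    """
    a = np.asarray(list(weekday), dtype=float)
    b = np.asarray(list(weekend), dtype=float)
    if a.shape != b.shape:
        raise ValueError("weekday and weekend vectors must be paired (same length)")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("need at least 2 complete pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        logger.warning("paired test: zero-variance non-zero differences (degenerate)")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


# Reference levels: male, no degree, <=30k income, sedentary occupation,
# part-time, car travel; age and wear time continuous.
ADJUSTED_MODEL_TERMS = (
    "female",
    "age_years",
    "degree",
    "income_gt_30k",
    "nonsedentary",
    "fulltime",
    "wear_minutes",
    "walk",
)


def _collinear_terms(X: pd.DataFrame) -> list[str]:
    cols = list(X.columns)
    bad = []
    kept: list[str] = []
    for c in cols:
        trial = X[kept + [c]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            bad.append(c)
        else:
            kept.append(c)
    return bad


def fit_adjusted_model(
    table: pd.DataFrame,
    outcome: str,
    terms: Sequence[str] = ADJUSTED_MODEL_TERMS,
) -> AdjustedModel:
    """OLS of a per-participant weekday outcome on travel mode and confounders.

    ``table`` has one row per participant with the outcome column plus the
    coded covariates in ``terms`` (walk dummy with car as reference; female,
    degree, income_gt_30k, nonsedentary, fulltime dummies; age_years and
    wear_minutes continuous). Returns coefficients with 95% CIs and p-values.
    """
    missing = [t for t in list(terms) + [outcome] if t not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    df = table[[outcome, *terms]].dropna()
    if len(df) <= len(terms) + 1:
        raise ValueError(
            f"only {len(df)} complete rows for {len(terms) + 1} parameters: model underdetermined"
        )
    X = df[list(terms)].astype(float)
    y = df[outcome].astype(float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        bad = _collinear_terms(Xc)
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=0.05)
    ests = tuple(
        TermEstimate(
            term=t,
            coef=float(res.params[t]),
            ci_low=float(ci.loc[t, 0]),
            ci_high=float(ci.loc[t, 1]),
            p=float(res.pvalues[t]),
        )
        for t in terms
    )
    return AdjustedModel(
        outcome=outcome, terms=ests, n=int(res.nobs), r_squared=float(res.rsquared)
    )


def percent_difference(mean_a: float, mean_b: float) -> float:
    """Percent by which ``mean_a`` exceeds ``mean_b``: 100·(a − b)/b."""
    if mean_b <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_a - mean_b) / mean_b


def day_level_comparison(
    day_table: pd.DataFrame,
    value_col: str = "mean_cpm",
    mode_col: str = "day_mode",
    modes: Sequence[str] = ("walk", "car"),
) -> GroupComparison:
    """One-way ANOVA at the day level: all walking days vs all car days.

    Each row is one participant-day labelled by that day's diary mode; days
    are pooled across participants without clustering.
    """
    values = {}
    for m in modes:
        vals = day_table.loc[day_table[mode_col] == m, value_col].dropna().to_numpy()
        if len(vals) == 0:
            raise ValueError(f"no days with mode {m!r}")
        values[m] = vals
    return compare_groups(values)
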