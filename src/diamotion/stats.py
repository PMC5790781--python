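"""Outcome statistics for diaphragm-motion profiles.

Covers the statistical layer of the analysis: ordinary least-squares
regressions of each length measure against lung CSA over the
respiratory cycle (slope S, intercept C, signed correlation R and the
two-sided p-value of the slope), percentage group differences,
covariate-adjusted two-group comparison, Pearson correlation with
spirometry, percentage coefficient of variation for observer
reliability, and a two-sided Wilcoxon rank-sum test with exact
small-sample enumeration.

No multiple-comparison correction is applied anywhere; reported
p-values are nominal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .measures import MeasurementProfile

__all__ = [
    "RegressionFit", "GroupComparison", "RankSumResult", "ObserverVariability",
    "linear_fit", "length_vs_csa", "percent_smaller", "group_compare",
    "pearson", "cv_percent", "rank_sum_exact", "observer_variability",
]

LENGTH_MEASURES = ("ANT", "CNT", "PST", "TDM", "DIA")
MIN_LENGTH_COLUMNS = ("ANT_min", "CNT_min", "PST_min", "DIA_min")


@dataclass(frozen=True)
class RegressionFit:
    """Simple OLS fit of a length measure against CSA.

    ``slope`` is in length units per CSA unit (mm/cm² in the pipeline),
    ``intercept`` the length at CSA = 0, ``r`` the signed Pearson
    correlation (NaN with ``r_defined=False`` for a constant response),
    ``p_value`` the two-sided t-test on the slope with n-2 df.
    """

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    measure: str | None = None
    r_defined: bool = True

    @property
    def abs_r(self) -> float:
        return abs(self.r)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison, optionally adjusted for one covariate.

    Without a covariate this is exactly the pooled-variance two-sample
    t-test expressed as a linear model.
    """

    effect: float                 # second group minus first, adjusted
    t_stat: float
    p_value: float                # two-sided
    covariate: str | None
    groups: tuple
    group_means: dict
    df_resid: int


@dataclass(frozen=True)
class RankSumResult:
    statistic: float              # rank sum of the first sample
    p_value: float                # two-sided
    mode: str                     # "exact" or "approx"
    n: int
    m: int


@dataclass
class ObserverVariability:
    """%CV table per observer x subject x measure, plus the
    inter-observer rank-sum comparison of the pooled %CV values."""

    cv_table: pd.DataFrame        # columns: observer, subject, measure, cv_pct
    rank_sum: RankSumResult

    @property
    def p_value(self) -> float:
        return self.rank_sum.p_value


def linear_fit(x, y, measure: str | None = None) -> RegressionFit:
    """Ordinary least squares of ``y`` on ``x`` via the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 points for a regression, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("x is constant; regression undefined")
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy == 0:
        # flat response: slope 0, correlation undefined
        return RegressionFit(slope=0.0, intercept=float(y.mean()), r=float("nan"),
                             p_value=float("nan"), n=n, measure=measure,
                             r_defined=False)
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return RegressionFit(slope=float(slope), intercept=intercept, r=float(r),
                         p_value=p, n=n, measure=measure)


def length_vs_csa(profile: MeasurementProfile) -> dict[str, RegressionFit]:
    """One regression per length measure (ANT/CNT/PST/TDM/DIA) vs CSA,
    over the valid frames of a profile."""
    if profile.n_valid < 3:
        raise ValueError("need >= 3 valid frames for regressions")
    x = profile.values("CSA")
    return {m: linear_fit(x, profile.values(m), measure=m)
            for m in LENGTH_MEASURES}


def percent_smaller(reference_mean: float, group_mean: float) -> float:
    """How much smaller ``group_mean`` is than ``reference_mean``, in %:
    ``100 * (1 - group/reference)``."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (1.0 - group_mean / reference_mean)


def group_compare(values, group_labels, covariate=None,
                  covariate_name: str = "covariate") -> GroupComparison:
    """Two-group linear-model comparison, optionally covariate-adjusted.

    Fits ``value ~ group (+ covariate)`` and reports the group term.
    With no covariate the result is identical to the pooled-variance
    two-sample t-test.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    dummy = (labels == groups[1]).astype(float)
    for g, cnt in zip(groups, (np.sum(dummy == 0), np.sum(dummy == 1))):
        if cnt < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    cols = [np.ones_like(y), dummy]
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != y.shape:
            raise ValueError("covariate length must match values")
        cols.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design matrix is rank-deficient "
            f"({covariate_name + ' is collinear with the intercept/group' if covariate is not None else 'degenerate grouping'})")

    import statsmodels.api as sm
    fit = sm.OLS(y, X).fit()
    means = {g: float(y[labels == g].mean()) for g in groups}
    return GroupComparison(effect=float(fit.params[1]), t_stat=float(fit.tvalues[1]),
                           p_value=float(fit.pvalues[1]),
                           covariate=covariate_name if covariate is not None else None,
                           groups=tuple(groups), group_means=means,
                           df_resid=int(fit.df_resid))


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value (t transform,
    n-2 df).  Raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    r = max(-1.0, min(1.0, sxy / math.sqrt(sxx * syy)))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return r, 2.0 * float(sps.t.sf(abs(t), n - 2))


def cv_percent(values) -> float:
    """Percentage coefficient of variation: 100 x sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values for a coefficient of variation")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError("mean must be positive for a %CV")
    return 100.0 * float(v.std(ddof=1)) / mean


def _exact_rank_sum_p(ranks_x_sum: float, n: int, N: int) -> float:
    """Two-sided exact p by full enumeration of rank assignments."""
    all_ranks = range(1, N + 1)
    sums = np.fromiter((sum(c) for c in combinations(all_ranks, n)), dtype=float)
    mean = n * (N + 1) / 2.0
    lo, hi = min(ranks_x_sum, 2 * mean - ranks_x_sum), max(ranks_x_sum, 2 * mean - ranks_x_sum)
    count = np.sum(sums <= lo + 1e-9) + np.sum(sums >= hi - 1e-9)
    return min(1.0, float(count) / sums.size)


def rank_sum_exact(x, y, mode: str = "auto") -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact p by enumeration of all C(n+m, n) rank assignments when
    ``n + m <= 16`` (requires tie-free pooled data); otherwise a normal
    approximation with continuity correction and midrank tie handling.
    The mode used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    N = n + m
    has_ties = np.unique(pooled).size < N

    if mode == "auto":
        mode = "exact" if (N <= 16 and not has_ties) else "approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("ties present: exact mode undefined, use mode='approx'")
        if N > 16:
            raise ValueError("exact enumeration limited to n + m <= 16")
        ranks = sps.rankdata(pooled)
        w = float(ranks[:n].sum())
        return RankSumResult(statistic=w, p_value=_exact_rank_sum_p(w, n, N),
                             mode="exact", n=n, m=m)
    if mode != "approx":
        raise ValueError(f"unknown mode {mode!r}")

    ranks = sps.rankdata(pooled)          # midranks under ties
    w = float(ranks[:n].sum())
    mean = n * (N + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (N * (N - 1))
    var = n * m / 12.0 * (N + 1 - tie_term)
    if var == 0:
        return RankSumResult(statistic=w, p_value=1.0, mode="approx", n=n, m=m)
    z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return RankSumResult(statistic=w, p_value=p, mode="approx", n=n, m=m)


def observer_variability(summary_table: pd.DataFrame) -> ObserverVariability:
    """Observer-reliability analysis of repeated pipeline runs.

    ``summary_table`` holds one row per (observer, subject, repeat) run
    with at least the columns ``observer``, ``subject`` and the four
    minimum-length columns ``ANT_min``, ``CNT_min``, ``PST_min``,
    ``DIA_min`` (mm), e.g. concatenated ``SummaryMeasures.to_frame()``
    rows.  Returns the %CV per observer x subject x measure and a
    two-sided rank-sum test comparing the pooled %CV distributions of
    the two observers.
    """
    required = {"observer", "subject", *MIN_LENGTH_COLUMNS}
    missing = required - set(summary_table.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    observers = sorted(summary_table["observer"].unique().tolist())
    if len(observers) != 2:
        raise ValueError(f"expected exactly 2 observers, got {observers}")
    subj_sets = [set(summary_table.loc[summary_table["observer"] == o, "subject"])
                 for o in observers]
    if subj_sets[0] != subj_sets[1]:
        raise ValueError("observers analysed different subject sets: "
                         f"{sorted(subj_sets[0] ^ subj_sets[1])}")

    rows = []
    for (obs, subj), grp in summary_table.groupby(["observer", "subject"]):
        if len(grp) < 2:
            raise ValueError(f"observer {obs!r}, subject {subj!r}: "
                             "need >= 2 repeats for a %CV")
        for col in MIN_LENGTH_COLUMNS:
            rows.append({"observer": obs, "subject": subj,
                         "measure": col, "cv_pct": cv_percent(grp[col].to_numpy())})
    cv_table = pd.DataFrame(rows)
    pooled = [cv_table.loc[cv_table["observer"] == o, "cv_pct"].to_numpy()
              for o in observers]
    result = rank_sum_exact(pooled[0], pooled[1], mode="auto")
    return ObserverVariability(cv_table=cv_table, rank_sum=result)
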