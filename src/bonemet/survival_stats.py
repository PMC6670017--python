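"""Group-comparison statistics and cause-specific survival analysis.

Survival uses death from prostate cancer as the event and death from other
causes (or being alive at last follow-up) as censoring, with the clock
starting at first androgen-deprivation therapy.  Kaplan-Meier estimation
and the log-rank test are backed by lifelines; the Cox proportional-hazards
fit uses the Breslow tie convention (statsmodels PHReg) and reports Wald
confidence intervals.

Group comparisons follow the small-cohort convention: Kruskal-Wallis as an
omnibus gate followed by pairwise Mann-Whitney U tests (exact p for groups
of up to 12 without ties), paired Wilcoxon signed-rank, Spearman rank
correlation, and the chi-square test for categorical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KmCurve",
    "km_estimate",
    "logrank",
    "cox_fit",
    "group_tests",
    "mann_whitney",
    "spearman",
    "chi_square",
]


# ----------------------------------------------------------------------
# Kaplan-Meier
# ----------------------------------------------------------------------

@dataclass
class KmCurve:
    """Product-limit survival curve with its median."""

    timeline: np.ndarray
    survival: np.ndarray
    median: float | None      # earliest time with S(t) <= 0.5; None if never
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` is 1 for an observed (cancer-death) event, 0 for censoring.
    The median is the earliest time at which the curve reaches 0.5 or below;
    ``None`` when the curve never crosses (e.g. everything censored).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if len(t) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"]
    median = kmf.median_survival_time_
    return KmCurve(
        timeline=surv.index.to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        median=None if np.isinf(median) else float(median),
        n=len(t),
        n_events=int(e.sum()),
    )


# ----------------------------------------------------------------------
# log-rank
# ----------------------------------------------------------------------

def logrank(groups: list[tuple]) -> dict:
    """k-group log-rank test over pooled event times.

    ``groups`` is a list of (times, events) pairs.  Returns the chi-square
    statistic, degrees of freedom and p value.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if len(t) == 0:
            raise ValueError(f"group {i} has zero subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), i))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return {
        "statistic": float(res.test_statistic),
        "df": len(groups) - 1,
        "p_value": float(res.p_value),
    }


# ----------------------------------------------------------------------
# Cox proportional hazards
# ----------------------------------------------------------------------

def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_months",
    event_col: str = "event",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Multivariate Cox model (Breslow ties) with Wald confidence intervals.

    Categorical covariates are dummy-coded against their first level.
    Returns a table with hazard ratios, CI bounds and p values per
    coefficient; non-convergence or separation surfaces as a warning
    carried in ``.attrs["converged"]``.
    """
    from statsmodels.duration.hazard_regression import PHReg

    df = records.dropna(subset=[time_col, event_col] + covariates).copy()
    X = pd.get_dummies(df[covariates], drop_first=True, dtype=float)
    n_events = int(df[event_col].sum())
    if n_events < X.shape[1]:
        raise ValueError("fewer events than parameters")
    model = PHReg(
        df[time_col].to_numpy(dtype=float),
        X.to_numpy(dtype=float),
        status=df[event_col].to_numpy(dtype=int),
        ties="breslow",
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit()
        if any("converge" in str(w.message).lower() for w in caught):
            converged = False
    z = stats.norm.ppf(1 - alpha / 2)
    coef = res.params
    se = res.bse
    if np.any(se > 1e3):
        converged = False  # likely separation: exploding standard errors
    out = pd.DataFrame(
        {
            "coef": coef,
            "hazard_ratio": np.exp(coef),
            "se": se,
            "hr_lower": np.exp(coef - z * se),
            "hr_upper": np.exp(coef + z * se),
            "p_value": 2 * stats.norm.sf(np.abs(coef / se)),
        },
        index=X.columns,
    )
    out.attrs["converged"] = converged
    out.attrs["n"] = len(df)
    out.attrs["n_events"] = n_events
    return out


# ----------------------------------------------------------------------
# univariate group tests
# ----------------------------------------------------------------------

def mann_whitney(x, y, exact_max_n: int = 12) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact p value when both groups have at most ``exact_max_n`` observations
    and no ties straddle the groups; otherwise the normal approximation with
    tie correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p_value": float(res.pvalue), "method": method}


def group_tests(values, groups, paired_with=None) -> dict:
    """Kruskal-Wallis omnibus gate followed by pairwise Mann-Whitney tests.

    Returns the Kruskal-Wallis H and p, and per-pair Mann-Whitney results
    (computed regardless of the gate; ``gate_passed`` records whether the
    omnibus test was significant at 0.05).  With ``paired_with`` given, a
    paired Wilcoxon signed-rank test of ``values`` against it is added
    instead of the group machinery.
    """
    v = np.asarray(values, dtype=float)
    if paired_with is not None:
        w = np.asarray(paired_with, dtype=float)
        if len(v) != len(w):
            raise ValueError("paired test needs equal-length vectors")
        if np.all(v == w):
            return {"wilcoxon_p": 1.0, "wilcoxon_stat": 0.0}
        res = stats.wilcoxon(v, w)
        return {"wilcoxon_p": float(res.pvalue), "wilcoxon_stat": float(res.statistic)}
    g = pd.Series(np.asarray(groups))
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [v[(g == lev).to_numpy()] for lev in levels]
    if all(np.array_equal(np.sort(s), np.sort(samples[0])) for s in samples):
        kw_h, kw_p = 0.0, 1.0
    else:
        kw_h, kw_p = stats.kruskal(*samples)
    pairwise = {
        f"{a}_vs_{b}": mann_whitney(samples[levels.index(a)], samples[levels.index(b)])
        for a, b in combinations(levels, 2)
    }
    return {
        "kruskal_h": float(kw_h),
        "kruskal_p": float(kw_p),
        "gate_passed": kw_p < 0.05,
        "pairwise": pairwise,
    }


def spearman(x, y) -> dict:
    """Spearman rank correlation with p value."""
    res = stats.spearmanr(x, y)
    return {"rho": float(res.statistic), "p_value": float(res.pvalue)}


def chi_square(table) -> dict:
    """Chi-square test of independence on a contingency table."""
    res = stats.chi2_contingency(np.asarray(table))
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "df": int(res.dof),
    }
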