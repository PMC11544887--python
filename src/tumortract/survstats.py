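"""Outcome analysis for tract-derived metrics.

Mirrors the analysis workflow used for the tumor cohort: univariate
ordinary-least-squares regression of overall survival (days) on continuous
metrics with beta, 95% CI and two-sided p; Welch two-sided t-tests for
binary strata; quartile stratification of each predictor; Kaplan-Meier
product-limit estimation per stratum; and k-sample log-rank tests between
quartile groups.  No multiple-testing correction is applied across the
univariate tests, matching the reporting convention this stage reproduces
(documented as a limitation).

Standard-model fitting is delegated to established implementations
(statsmodels OLS, scipy's Welch t, lifelines' Kaplan-Meier and log-rank);
this module contributes the cohort-level workflow and the quartile rule.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "KMCurve",
    "ols_survival",
    "welch_ttest",
    "quartile_groups",
    "km_estimate",
    "logrank_test",
    "quartile_survival_analysis",
]


@dataclass(frozen=True)
class RegressionResult:
    beta: float
    ci95: tuple
    p_value: float


@dataclass
class KMCurve:
    """Product-limit survival estimate S(t) at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray


def ols_survival(os_days, x) -> RegressionResult:
    """OLS slope of survival on a continuous predictor with t-based 95% CI
    and two-sided p."""
    y = np.asarray(os_days, dtype=float)
    xv = np.asarray(x, dtype=float)
    if len(y) != len(xv) or len(y) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(xv) == 0:
        raise ValueError("predictor is constant")
    X = sm.add_constant(xv)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)[1]
    return RegressionResult(beta=float(fit.params[1]),
                            ci95=(float(ci[0]), float(ci[1])),
                            p_value=float(fit.pvalues[1]))


def welch_ttest(a, b) -> dict:
    """Welch unequal-variance two-sided t-test (Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):   # both groups zero-variance
        t, p = 0.0, 1.0
    return {"t": float(t), "p": float(p)}


def quartile_groups(values) -> np.ndarray:
    """Quartile labels Q1..Q4 from type-7 (linear interpolation) sample
    quantiles; ties at a cut point go to the lower group."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values for quartiles")
    cuts = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation (type 7)
    if np.ptp(v) == 0:
        warnings.warn("all values identical; every subject labeled Q1")
    labels = np.array([f"Q{1 + int((x > cuts).sum())}" for x in v])
    return labels


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with right censoring.

    Subjects censored exactly at an event time remain at risk for that
    event time (the standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    n_events = ev["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMCurve(event_times=event_times, at_risk=at_risk,
                   events=n_events, survival=surv)


def logrank_test(groups) -> dict:
    """k-sample log-rank test.

    Parameters
    ----------
    groups : sequence of (times, events) pairs, one per group.

    Returns
    -------
    dict with ``chi2``, ``df`` (k - 1) and the chi-square upper-tail ``p``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times, events, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if len(t) == 0:
            raise ValueError("a group has zero subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), gi))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if not events.any():
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(times, labels, events)
    return {"chi2": float(res.test_statistic),
            "df": len(groups) - 1,
            "p": float(res.p_value)}


def quartile_survival_analysis(
    cohort: pd.DataFrame,
    metric: str,
    time_col: str = "os_days",
    event_col: str = "event",
) -> dict:
    """Quartile-stratified Kaplan-Meier comparison for one metric.

    Returns the quartile labels, a KMCurve per quartile, the per-quartile
    median survival, and the 4-group log-rank test.
    """
    labels = quartile_groups(cohort[metric].to_numpy())
    curves, medians, groups = {}, {}, []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        sel = labels == q
        if not sel.any():
            continue
        t = cohort.loc[sel, time_col].to_numpy(dtype=float)
        e = cohort.loc[sel, event_col].to_numpy(dtype=bool)
        curves[q] = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, event_observed=e)
        medians[q] = float(kmf.median_survival_time_)
        groups.append((t, e))
    lr = logrank_test(groups)
    return {"labels": labels, "curves": curves,
            "median_survival": medians, "logrank": lr}
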