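"""Cohort stratification by CAF-subset scores and Kaplan-Meier analysis.

Patients are stratified into tertiles (low/medium/high) of the relative
abundance of two CAF subsets — the difference of their per-patient subset
scores — and overall survival is compared across strata with the
product-limit (Kaplan-Meier) estimator and the k-sample log-rank test.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "relative_abundance",
    "tertile_stratify",
    "km_estimate",
    "logrank_test",
    "stratified_km_report",
]

STRATA = ("low", "medium", "high")


def relative_abundance(score_a, score_b):
    """Relative abundance of two CAF subsets: score_a - score_b."""
    return np.asarray(score_a, dtype=float) - np.asarray(score_b, dtype=float)


def tertile_stratify(values) -> np.ndarray:
    """Split values into low/medium/high at the empirical 1/3 and 2/3 quantiles.

    Uses linear-interpolation quantiles; ties go to the lower stratum, so a
    constant vector is all "low" (with a warning). Requires n >= 3.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("tertile stratification needs at least 3 values")
    q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    if q1 == q2:
        warnings.warn("degenerate tertile cuts (tied quantiles)", stacklevel=2)
    labels = np.where(v <= q1, "low", np.where(v <= q2, "medium", "high"))
    return labels


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival curve with at-risk counts.

    Returns a step-function table with one row per distinct time:
    columns time, survival (S(t) = prod over t_i <= t of 1 - d_i/n_i),
    at_risk, events, censored.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
        }
    )
    return out.reset_index(drop=True)


def logrank_test(groups: dict[str, tuple]) -> dict:
    """k-sample log-rank test across survival groups.

    ``groups`` maps group name -> (times, events). Returns the chi-square
    statistic, degrees of freedom (k - 1) and p-value.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for name in sorted(groups):
        t, e = groups[name]
        times.append(np.asarray(t, dtype=float))
        events.append(np.asarray(e, dtype=int))
        labels.append(np.full(len(t), name, dtype=object))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return {
        "statistic": float(res.test_statistic),
        "df": len(groups) - 1,
        "p_value": float(res.p_value),
    }


def stratified_km_report(
    cohort: pd.DataFrame,
    subset_a: str,
    subset_b: str,
    time_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Tertile-stratified Kaplan-Meier comparison of relative CAF abundance.

    ``cohort`` has per-patient survival columns and one score column per
    subset. Rows with missing scores or survival fields are dropped
    (complete cases, logged). Returns per-stratum KM curves (plot-ready),
    the overall log-rank result, pairwise log-rank tests, and per-stratum
    median survival.
    """
    needed = [time_col, event_col, subset_a, subset_b]
    missing = set(needed) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")
    data = cohort[needed].copy()
    n_before = len(data)
    data = data.dropna()
    if len(data) < n_before:
        logger.info("dropped %d incomplete rows", n_before - len(data))

    rel = relative_abundance(data[subset_a], data[subset_b])
    strata = tertile_stratify(rel)
    data = data.assign(relative_abundance=rel, stratum=strata)

    curves = {}
    medians = {}
    groups = {}
    for name in STRATA:
        sub = data[data["stratum"] == name]
        if len(sub) == 0:
            continue
        t = sub[time_col].to_numpy(dtype=float)
        e = sub[event_col].to_numpy(dtype=int)
        curves[name] = km_estimate(t, e).assign(stratum=name)
        groups[name] = (t, e)
        kmf = KaplanMeierFitter().fit(t, event_observed=e)
        medians[name] = float(kmf.median_survival_time_)

    overall = logrank_test(groups) if len(groups) >= 2 else None
    pairwise = []
    names = [n for n in STRATA if n in groups]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = logrank_test({a: groups[a], b: groups[b]})
            pairwise.append({"group_a": a, "group_b": b, **res})

    return {
        "strata": data[["relative_abundance", "stratum"]],
        "curves": pd.concat(curves.values(), ignore_index=True) if curves else pd.DataFrame(),
        "logrank": overall,
        "pairwise_logrank": pd.DataFrame(pairwise),
        "median_survival": medians,
    }
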