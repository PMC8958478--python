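"""Cohort-level descriptive and inferential statistics.

Per-condition summaries of the network metrics (mean/SD, median/IQR, total
connections), a tie-corrected Friedman rank test comparing the three
conditions measured on the same practices, the Spearman rank correlation
between density and centralization, and tabulations of information exchange
with occupational groups outside the practice and with cardiologists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import NetworkMetrics
from .roster import (
    CARDIOLOGIST_CONDITIONS,
    CONDITIONS,
    Cohort,
    Condition,
    OccupationalGroup,
    Role,
)

__all__ = [
    "MetricSummary",
    "ConditionSummary",
    "FriedmanResult",
    "CardiologistSummary",
    "condition_summary",
    "summary_table",
    "friedman_test",
    "spearman_correlation",
    "external_exchange_table",
    "cardiologist_summary",
]

#: Metric columns summarised per condition, in reporting order.
_METRIC_FIELDS = ("reciprocity", "n_edges", "density", "centralization")


@dataclass(frozen=True)
class MetricSummary:
    """Five-number descriptive summary of one metric over included practices."""

    n: int
    mean: float
    sd: Optional[float]  # None when n < 2
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class ConditionSummary:
    condition: Condition
    n_networks: int
    total_connections: int
    metrics: dict[str, MetricSummary]


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    n_blocks: int
    tie_corrected: bool


@dataclass(frozen=True)
class RoleMean:
    n: int
    mean: float
    sd: Optional[float]


@dataclass(frozen=True)
class CardiologistSummary:
    """Monthly cardiologist-contact counts, practice-level and by role."""

    condition: Condition
    n_practices: int
    practice_mean: float
    practice_sd: Optional[float]
    count_min: int
    count_max: int
    by_role: dict[str, RoleMean]  # keys: "physician", "non_physician"


def _summarize(values: Sequence[float]) -> MetricSummary:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return MetricSummary(
        n=arr.size,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else None,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def condition_summary(
    metrics: Sequence[NetworkMetrics], condition: Condition
) -> ConditionSummary:
    """Descriptive summary of one condition's networks.

    Sample SD (n-1 denominator); median and IQR by linear-interpolation
    percentiles. Undefined reciprocities are skipped and the effective n is
    reported for that row.
    """
    sub = [m for m in metrics if m.condition is condition]
    if not sub:
        raise ValueError(f"no metrics for condition {condition.value}")
    out: dict[str, MetricSummary] = {
        "n_edges": _summarize([m.n_edges for m in sub]),
        "density": _summarize([m.density for m in sub]),
        "centralization": _summarize([m.centralization for m in sub]),
    }
    recips = [m.reciprocity for m in sub if m.reciprocity is not None]
    if recips:
        out["reciprocity"] = _summarize(recips)
    return ConditionSummary(
        condition=condition,
        n_networks=len(sub),
        total_connections=sum(m.n_edges for m in sub),
        metrics=out,
    )


def summary_table(
    summaries: Sequence[ConditionSummary],
    friedman: Optional[dict[str, FriedmanResult]] = None,
) -> pd.DataFrame:
    """Flat per-condition, per-metric summary table (study Table-2 style)."""
    rows = []
    for s in summaries:
        for name in _METRIC_FIELDS:
            if name not in s.metrics:
                continue
            m = s.metrics[name]
            rows.append(
                {
                    "condition": s.condition.value,
                    "metric": name,
                    "n": m.n,
                    "mean": round(m.mean, 2),
                    "sd": None if m.sd is None else round(m.sd, 2),
                    "median": round(m.median, 2),
                    "q1": round(m.q1, 2),
                    "q3": round(m.q3, 2),
                    "total_connections": s.total_connections if name == "n_edges" else None,
                    "friedman_p": (
                        round(friedman[name].p_value, 4)
                        if friedman is not None and name in friedman
                        else None
                    ),
                }
            )
    return pd.DataFrame(rows)


def friedman_test(values) -> FriedmanResult:
    """Friedman rank test across k related samples, with tie correction.

    ``values`` is an (n_blocks x k) matrix: one row per practice, one column
    per condition. Rows containing missing values (NaN) are dropped with a
    warning. Within each row, mid-ranks are assigned; the statistic

        chi2 = [12 / (n k (k+1))] * sum_j R_j^2  -  3 n (k+1)

    is divided by the tie-correction factor
    ``C = 1 - sum(t^3 - t) / (n k (k^2 - 1))`` and referred to the asymptotic
    chi-square distribution with k-1 degrees of freedom. When every row is
    completely tied (C = 0) the statistic is 0 and p = 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("friedman_test expects an (n_blocks x k) matrix with k >= 2")
    complete = ~np.isnan(arr).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"friedman_test: dropping {n_dropped} row(s) with missing condition values",
            stacklevel=2,
        )
    arr = arr[complete]
    n, k = arr.shape
    if n < 2:
        raise ValueError(f"friedman_test needs at least 2 complete rows, got {n}")

    ranks = sps.rankdata(arr, axis=1)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)

    tie_sum = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))

    if correction <= 0.0:
        # every row completely tied: no evidence of any difference
        statistic = 0.0
        p_value = 1.0
    else:
        statistic = chi2 / correction
        p_value = float(sps.chi2.sf(statistic, k - 1))
    return FriedmanResult(
        statistic=statistic,
        df=k - 1,
        p_value=p_value,
        n_blocks=n,
        tie_corrected=tie_sum > 0,
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with t-approximation p-value.

    Raises on unequal lengths, n < 3 or a constant input vector (the rank
    correlation is undefined there, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("spearman_correlation needs at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("spearman correlation undefined for a constant input vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def external_exchange_table(cohort: Cohort) -> pd.DataFrame:
    """Weekly exchange with occupational groups outside the practice.

    One row per group x condition x stratum (overall / physician /
    practice_assistant): count and percentage of responding individuals in
    that stratum who marked the group. Non-respondents are excluded from the
    denominators; percentages are to one decimal.
    """
    respondents = [m for p in cohort.practices for m in p.members if m.responded]
    strata = {
        "overall": respondents,
        "physician": [m for m in respondents if m.role is Role.PHYSICIAN],
        "practice_assistant": [m for m in respondents if m.role is Role.PRACTICE_ASSISTANT],
    }
    rows = []
    for group in OccupationalGroup:
        for condition in CONDITIONS:
            for stratum, members in strata.items():
                denom = len(members)
                n = sum(group in m.external_groups[condition] for m in members)
                rows.append(
                    {
                        "group": group.value,
                        "condition": condition.value,
                        "stratum": stratum,
                        "n": n,
                        "pct": round(100.0 * n / denom, 1) if denom else math.nan,
                        "denominator": denom,
                    }
                )
    return pd.DataFrame(rows)


def cardiologist_summary(cohort: Cohort, condition: Condition) -> CardiologistSummary:
    """Monthly cardiologist contacts for CHD or CHF.

    Practice level: the mean over practices of the practice's member-mean
    count (members with missing counts excluded; practices with no observed
    count excluded). Role level: individual means for physicians and
    non-physicians. The reported range is over individual raw counts.
    """
    if condition not in CARDIOLOGIST_CONDITIONS:
        raise ValueError(f"cardiologist counts exist for CHD and CHF only, got {condition.value}")
    practice_means = []
    counts: list[int] = []
    by_role_values: dict[str, list[int]] = {"physician": [], "non_physician": []}
    for p in cohort.practices:
        observed = [
            m.cardiologists_monthly[condition]
            for m in p.members
            if m.cardiologists_monthly[condition] is not None
        ]
        if observed:
            practice_means.append(float(np.mean(observed)))
            counts.extend(observed)
        for m in p.members:
            v = m.cardiologists_monthly[condition]
            if v is None:
                continue
            key = "physician" if m.role is Role.PHYSICIAN else "non_physician"
            by_role_values[key].append(v)
    if not practice_means:
        raise ValueError(f"no cardiologist counts observed for {condition.value}")
    by_role = {
        key: RoleMean(
            n=len(vals),
            mean=float(np.mean(vals)),
            sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
        )
        for key, vals in by_role_values.items()
        if vals
    }
    return CardiologistSummary(
        condition=condition,
        n_practices=len(practice_means),
        practice_mean=float(np.mean(practice_means)),
        practice_sd=float(np.std(practice_means, ddof=1)) if len(practice_means) > 1 else None,
        count_min=min(counts),
        count_max=max(counts),
        by_role=by_role,
    )
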