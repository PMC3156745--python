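"""Univariate screening statistics: Spearman correlation with survival time,
Kaplan-Meier product-limit curves, the K-sample log-rank test, and the
three-way survival grouping (<=12 months / intermediate / >=60 months) used to
anchor all downstream classification tables.

Censoring is handled where it matters (Kaplan-Meier, log-rank) and deliberately
ignored by the rank correlation: the score construction treats observed
follow-up as the outcome, which is defensible only when censored times are long
relative to the grouping horizon — the situation these cohorts are in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import UndefinedStatisticError

#: Month boundaries of the prognosis groups: short survival (<= 12 months,
#: unambiguously bad), long survival (>= 60 months, unambiguously good), and
#: the intermediate band in between where prognosis is left undefined.
SHORT_SURVIVAL_MONTHS = 12.0
LONG_SURVIVAL_MONTHS = 60.0

GROUP_SHORT = "le12"
GROUP_MID = "mid"
GROUP_LONG = "ge60"


@dataclass(frozen=True)
class SpearmanResult:
    variable: str
    r_s: float
    p_value: float
    n: int


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimates at each distinct event time."""

    time_points: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass(frozen=True)
class LogRankResult:
    variable: str
    statistic: float
    df: int
    p_value: float


def spearman(
    x, t, *, variable: str = "", method: str = "asymptotic"
) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation between a covariate and survival.

    Ties get mid-ranks, so ``r_s`` equals the Pearson correlation of the rank
    vectors. ``method="asymptotic"`` gives the two-sided p-value from the
    t-approximation ``t* = r_s * sqrt((n-2)/(1-r_s^2))`` on ``n-2`` df;
    ``method="exact"`` runs the exact pairing-permutation test (only sensible
    for n <= 10).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.shape != t.shape or x.ndim != 1:
        raise UndefinedStatisticError("spearman: x and t must be equal-length vectors")
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("spearman: need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(t) == 0:
        raise UndefinedStatisticError(
            f"spearman: constant input for {variable or 'x'!r}; correlation undefined"
        )
    if method == "exact":
        if n > 9:
            raise UndefinedStatisticError(
                "exact permutation p-value is only supported for n <= 9"
            )
        from itertools import permutations

        rx = stats.rankdata(x) - (n + 1) / 2
        rt = stats.rankdata(t) - (n + 1) / 2
        denom = np.sqrt((rx @ rx) * (rt @ rt))
        r_obs = float((rx @ rt) / denom)
        perms = np.array(list(permutations(range(n))))
        r_all = (rx[perms] @ rt) / denom
        p = float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))
        return SpearmanResult(variable, r_obs, p, n)
    res = stats.spearmanr(x, t)
    return SpearmanResult(variable, float(res.statistic), float(res.pvalue), n)


def kaplan_meier(times, events) -> KMCurve:
    """Product-limit survival estimator; censored rows leave the risk set
    after their follow-up time without contributing an event."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise UndefinedStatisticError("kaplan_meier: empty input")
    if np.any(times <= 0):
        raise UndefinedStatisticError("kaplan_meier: survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    t = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy(dtype=float)
    return KMCurve(
        time_points=t,
        survival_prob=surv,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
    )


def logrank(times, events, group, *, variable: str = "") -> LogRankResult:
    """K-sample log-rank test (observed minus expected events over pooled
    event times, hypergeometric variance, chi-square on K-1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    labels, counts = np.unique(group, return_counts=True)
    if labels.size < 2:
        raise UndefinedStatisticError("logrank: need at least 2 non-empty groups")
    if events.sum() == 0:
        raise UndefinedStatisticError("logrank: no observed events")
    res = multivariate_logrank_test(times, group, events)
    return LogRankResult(
        variable=variable,
        statistic=float(res.test_statistic),
        df=int(labels.size - 1),
        p_value=float(res.p_value),
    )


def assign_survival_group(time: float, event: int) -> str:
    """Prognosis group from observed follow-up: ``le12`` if time <= 12 months,
    ``ge60`` if time >= 60 months, ``mid`` otherwise.

    Censored patients are grouped by their observed follow-up: someone censored
    beyond 60 months has demonstrably survived >= 60, while a censoring time
    inside (12, 60) leaves the true group unknown and the patient sits in
    ``mid`` like any other intermediate-survival case.
    """
    if not time > 0:
        raise UndefinedStatisticError("assign_survival_group: time must be > 0")
    if time <= SHORT_SURVIVAL_MONTHS:
        return GROUP_SHORT
    if time >= LONG_SURVIVAL_MONTHS:
        return GROUP_LONG
    return GROUP_MID


def survival_groups(times, events) -> list[str]:
    """Vectorised `assign_survival_group` over a cohort."""
    return [assign_survival_group(t, e) for t, e in zip(times, events)]
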