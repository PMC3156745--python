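"""Proportional-hazards comparator for the correlation-based score.

The model is the usual Cox form lambda(t, X) = lambda0(t) * exp(X . beta),
fitted by partial-likelihood maximisation (Breslow tie handling by default,
matching the SAS PHREG convention; Efron available). Variable selection is
automatic backward elimination: refit after removing the variable with the
largest Wald p-value for as long as that p-value exceeds the removal
threshold. Classification uses only the linear predictor X . beta on the
original covariate coding — lower values mean lower hazard, longer survival —
so the baseline hazard is never estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort, PatientRecord
from .errors import ConvergenceError, UndefinedStatisticError, ValidationError

#: Binary cut-off on the linear predictor: <= -5.5 is a good prognosis.
DEFAULT_COX_BINARY_CUTOFF = -5.5
#: Three-class preset: below `low` is low risk, above `high` is high risk,
#: boundaries fall to intermediate (strict inequalities).
COX_CLASS_PRESET = {"low": -6.0, "high": -4.5}

CLASS_LOW = "low"
CLASS_INTERMEDIATE = "intermediate"
CLASS_HIGH = "high"
CLASS_GOOD = "good"
CLASS_BAD = "bad"


@dataclass
class CoxModel:
    """Backward-selected proportional-hazards fit."""

    variables: list[str]
    beta: dict[str, float]
    p_values: dict[str, float]
    elimination_trace: list[tuple[str, float]] = field(default_factory=list)
    ties: str = "breslow"


@dataclass(frozen=True)
class CoxScore:
    patient_id: str
    score: float
    risk_class: str
    binary_class: str


def _fit_once(times, events, X, names, ties):
    """One partial-likelihood maximisation; returns (beta, p) arrays."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.PHReg(times, X, status=events, ties=ties)
        try:
            res = model.fit(disp=False)
        except Exception as exc:  # singular information, monotone likelihood
            raise ConvergenceError(
                f"partial likelihood failed to converge for {list(names)}: {exc}"
            ) from None
    beta = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    bad = ~np.isfinite(beta) | ~np.isfinite(se) | (np.abs(beta) > 50)
    if bad.any():
        culprit = names[int(np.flatnonzero(bad)[0])]
        raise ConvergenceError(
            f"monotone likelihood / separation suspected for variable {culprit!r}"
        )
    return beta, np.asarray(res.pvalues, dtype=float)


def fit_cox_backward(
    cohort: Cohort,
    candidates: list[str],
    p_remove: float = 0.05,
    *,
    ties: str = "breslow",
) -> CoxModel:
    """Fit on all candidates, then iteratively drop the variable with the
    largest Wald p-value while it exceeds ``p_remove``, refitting after each
    removal. Deterministic: p-value ties are broken by candidate-list order
    (the first maximum wins). Returns an empty model (all betas removed) when
    nothing survives selection."""
    if not candidates:
        raise ValidationError("fit_cox_backward: empty candidate list")
    times = np.asarray(cohort.survival_times, dtype=float)
    events = np.asarray(cohort.events, dtype=int)
    if events.sum() < 2:
        raise UndefinedStatisticError("fit_cox_backward: need at least 2 events")
    columns = {name: np.asarray(cohort.column(name), dtype=float) for name in candidates}
    for name, col in columns.items():
        if np.ptp(col) == 0:
            raise ValidationError(f"candidate {name!r} is constant")

    current = list(candidates)
    trace: list[tuple[str, float]] = []
    beta = np.empty(0)
    pvals = np.empty(0)
    while current:
        X = np.column_stack([columns[name] for name in current])
        beta, pvals = _fit_once(times, events, X, current, ties)
        worst = int(np.argmax(pvals))
        if pvals[worst] <= p_remove:
            break
        trace.append((current[worst], float(pvals[worst])))
        del current[worst]
    if not current:
        return CoxModel(variables=[], beta={}, p_values={}, elimination_trace=trace, ties=ties)
    return CoxModel(
        variables=current,
        beta={name: float(b) for name, b in zip(current, beta)},
        p_values={name: float(p) for name, p in zip(current, pvals)},
        elimination_trace=trace,
        ties=ties,
    )


def linear_predictor(beta: dict[str, float], patient: PatientRecord) -> float:
    total = 0.0
    for name, b in beta.items():
        if name not in patient.covariates:
            raise ValidationError(
                f"patient {patient.patient_id!r} lacks covariate {name!r}"
            )
        total += b * patient.covariates[name]
    return total


def cox_score(model: CoxModel, patient: PatientRecord) -> CoxScore:
    """Linear predictor X . beta on the original (unscaled) covariate coding,
    with its binary and three-class risk labels."""
    value = linear_predictor(model.beta, patient)
    return CoxScore(
        patient_id=patient.patient_id,
        score=value,
        risk_class=classify_cox(value),
        binary_class=classify_cox_binary(value),
    )


def score_cohort(model: CoxModel, cohort: Cohort) -> list[CoxScore]:
    return [cox_score(model, p) for p in cohort.patients]


def classify_cox(score: float, preset: dict | None = None) -> str:
    """Three risk classes on the linear predictor; strict boundaries, so both
    cut-off values themselves fall to intermediate."""
    cfg = preset or COX_CLASS_PRESET
    if score < cfg["low"]:
        return CLASS_LOW
    if score > cfg["high"]:
        return CLASS_HIGH
    return CLASS_INTERMEDIATE


def classify_cox_binary(score: float, cutoff: float = DEFAULT_COX_BINARY_CUTOFF) -> str:
    """Binary prognosis on the linear predictor: good iff score <= cutoff."""
    return CLASS_GOOD if score <= cutoff else CLASS_BAD
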