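"""The correlation-weighted individual risk score (ISIR) and its pipeline:
variable screening, scale normalisation, scoring, risk classes, and
leave-one-out cross-validation.

The score treats risk as the balance between *aggressive* covariates (those
with a significant negative Spearman correlation to survival time — larger
value, shorter survival) and *protective* covariates (significant positive
correlation). Each covariate is first divided by its number of possible
realizations so that four-level stage components and binary flags live on a
common [0, 1] scale. The score is then

    ISIR = (sum_i w_i * x_i / d_i) / (sum_i w_i)
           ---------------------------------------   with  w_i = |r_S(x_i, t)|
    over aggressive variables, divided by the same
    weighted average over protective variables with v_j = r_S(y_j, t) > 0.

Large ISIR means the aggressive side dominates the protective side: high risk.
Dividing by the weight sums makes the score invariant to rescaling all weights
on either side, which is what lets cut-offs transfer between cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .cohort import Cohort, PatientRecord, VariableSpec
from .errors import UndefinedScoreError, UndefinedStatisticError, ValidationError
from .survival import GROUP_LONG, GROUP_MID, GROUP_SHORT, spearman, survival_groups

ROLE_AGGRESSIVE = "aggressive"
ROLE_PROTECTIVE = "protective"
ROLE_EXCLUDED = "excluded"

CLASS_LOW = "low"
CLASS_INTERMEDIATE = "intermediate"
CLASS_HIGH = "high"
CLASS_GOOD = "good"
CLASS_BAD = "bad"
UNCLASSIFIABLE = "unclassifiable"

#: Three-class cut-off presets for the score. "methods" is the defining
#: preset (low <= 0.25, high >= 0.5, boundaries included); "table" is the
#: alternative used for the printed contingency table (low < 0.4, high > 0.8,
#: boundaries falling to intermediate).
CUTOFF_PRESETS: dict[str, dict] = {
    "methods": {"low": 0.25, "high": 0.5, "inclusive": True},
    "table": {"low": 0.4, "high": 0.8, "inclusive": False},
}
DEFAULT_BINARY_CUTOFF = 0.5


@dataclass(frozen=True)
class VariableScreen:
    """One candidate's screening outcome."""

    name: str
    r_s: float
    p_value: float
    n: int
    role: str


@dataclass
class ScreeningResult:
    results: list[VariableScreen]
    alpha: float

    def by_role(self, role: str) -> list[VariableScreen]:
        return [r for r in self.results if r.role == role]

    @property
    def aggressive(self) -> list[VariableScreen]:
        return self.by_role(ROLE_AGGRESSIVE)

    @property
    def protective(self) -> list[VariableScreen]:
        return self.by_role(ROLE_PROTECTIVE)


@dataclass(frozen=True)
class WeightedVariable:
    name: str
    weight: float  # > 0; |r_S| for aggressive, r_S for protective
    divisor: int


@dataclass
class IsirModel:
    """A fitted score: weighted aggressive/protective variable lists."""

    aggressive: list[WeightedVariable]
    protective: list[WeightedVariable]
    alpha: float = 0.05
    normalize: bool = True  # divide each side by its weight sum
    cutoff_preset: str = "methods"
    binary_cutoff: float = DEFAULT_BINARY_CUTOFF
    screening: ScreeningResult | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.protective:
            raise UndefinedScoreError(
                "ISIR undefined: no protective variable (empty denominator)"
            )
        for side in (self.aggressive, self.protective):
            for v in side:
                if not v.weight > 0:
                    raise ValidationError(f"weight for {v.name!r} must be > 0")

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.aggressive + self.protective]


@dataclass(frozen=True)
class RiskScore:
    patient_id: str
    isir: float
    risk_class: str
    binary_class: str


def scale_value(value: int, spec: VariableSpec) -> float:
    """Covariate value divided by its number of possible realizations."""
    if value not in spec.admissible_values:
        raise ValidationError(
            f"value {value} not admissible for {spec.name!r} "
            f"(allowed {spec.admissible_values})"
        )
    return value / spec.divisor


def screen_variables(
    cohort: Cohort, candidates: Sequence[str], alpha: float = 0.05
) -> ScreeningResult:
    """Label each candidate aggressive / protective / excluded by the sign and
    significance of its Spearman correlation with observed survival time.

    Candidates that are constant in the cohort cannot carry a correlation and
    are excluded (r_s reported as NaN).
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    t = cohort.survival_times
    out = []
    for name in candidates:
        x = cohort.column(name)
        try:
            res = spearman(x, t, variable=name)
        except UndefinedStatisticError:
            out.append(VariableScreen(name, math.nan, math.nan, len(t), ROLE_EXCLUDED))
            continue
        if res.p_value < alpha and res.r_s < 0:
            role = ROLE_AGGRESSIVE
        elif res.p_value < alpha and res.r_s > 0:
            role = ROLE_PROTECTIVE
        else:
            role = ROLE_EXCLUDED
        out.append(VariableScreen(name, res.r_s, res.p_value, res.n, role))
    return ScreeningResult(out, alpha)


def fit_isir(
    cohort: Cohort,
    candidates: Sequence[str],
    alpha: float = 0.05,
    *,
    normalize: bool = True,
    cutoff_preset: str = "methods",
    binary_cutoff: float = DEFAULT_BINARY_CUTOFF,
) -> IsirModel:
    """Screen the candidates, then weight the selected variables by their
    training-cohort Spearman correlations (absolute value on the aggressive
    side). Raises ``UndefinedScoreError`` when no protective variable is
    significant — the score's denominator would be empty."""
    if len(cohort) < 3:
        raise ValidationError("fit_isir: need at least 3 patients")
    if not candidates:
        raise ValidationError("fit_isir: empty candidate list")
    screening = screen_variables(cohort, candidates, alpha)
    aggressive = [
        WeightedVariable(r.name, abs(r.r_s), cohort.spec(r.name).divisor)
        for r in screening.aggressive
    ]
    protective = [
        WeightedVariable(r.name, r.r_s, cohort.spec(r.name).divisor)
        for r in screening.protective
    ]
    return IsirModel(
        aggressive=aggressive,
        protective=protective,
        alpha=alpha,
        normalize=normalize,
        cutoff_preset=cutoff_preset,
        binary_cutoff=binary_cutoff,
        screening=screening,
    )


def _weighted_side(patient: PatientRecord, side: Sequence[WeightedVariable], normalize: bool) -> float:
    total = 0.0
    wsum = 0.0
    for v in side:
        if v.name not in patient.covariates:
            raise ValidationError(
                f"patient {patient.patient_id!r} lacks covariate {v.name!r}"
            )
        total += v.weight * (patient.covariates[v.name] / v.divisor)
        wsum += v.weight
    if normalize and wsum > 0:
        return total / wsum
    return total


def isir_score(model: IsirModel, patient: PatientRecord) -> RiskScore:
    """Score one patient: weighted mean of scaled aggressive values over the
    weighted mean of scaled protective values."""
    numerator = _weighted_side(patient, model.aggressive, model.normalize)
    denominator = _weighted_side(patient, model.protective, model.normalize)
    if denominator <= 0:
        raise UndefinedScoreError(
            f"patient {patient.patient_id!r}: protective side is zero; "
            "ISIR undefined"
        )
    value = numerator / denominator
    return RiskScore(
        patient_id=patient.patient_id,
        isir=value,
        risk_class=classify_risk(value, model.cutoff_preset),
        binary_class=classify_binary(value, model.binary_cutoff),
    )


def score_cohort(model: IsirModel, cohort: Cohort) -> list[RiskScore]:
    return [isir_score(model, p) for p in cohort.patients]


def classify_risk(score: float, preset: str = "methods") -> str:
    """Three risk classes from a cut-off preset; boundary handling follows the
    preset's definition (inclusive for "methods", strict for "table")."""
    if score < 0:
        raise ValidationError(f"risk score must be >= 0, got {score}")
    cfg = CUTOFF_PRESETS[preset]
    low, high, inclusive = cfg["low"], cfg["high"], cfg["inclusive"]
    if (score <= low) if inclusive else (score < low):
        return CLASS_LOW
    if (score >= high) if inclusive else (score > high):
        return CLASS_HIGH
    return CLASS_INTERMEDIATE


def classify_binary(score: float, cutoff: float = DEFAULT_BINARY_CUTOFF) -> str:
    """Binary prognosis: ``good`` iff score <= cutoff (the boundary counts as
    good), ``bad`` otherwise."""
    return CLASS_GOOD if score <= cutoff else CLASS_BAD


@dataclass(frozen=True)
class LooFold:
    """One held-out patient's cross-validated prediction."""

    patient_id: str
    survival_group: str
    isir: float | None
    risk_class: str  # 3-class label or "unclassifiable"
    binary_class: str  # good / bad / "unclassifiable"
    note: str = ""


@dataclass
class LooReport:
    folds: list[LooFold]
    alpha: float
    cutoff: float

    @property
    def n(self) -> int:
        return len(self.folds)

    def clear_prognosis_folds(self) -> list[LooFold]:
        """Folds whose survival group is unambiguous (<=12 or >=60 months)."""
        return [f for f in self.folds if f.survival_group in (GROUP_SHORT, GROUP_LONG)]

    def correct_counts(self) -> tuple[int, int, int, int]:
        """(correct among le12, n le12, correct among ge60, n ge60).

        A short-survival patient is counted correct when predicted ``bad``, a
        long-survival patient when predicted ``good``. Unclassifiable folds
        stay in the denominators: a score that could not be formed did not
        classify the patient correctly.
        """
        short = [f for f in self.folds if f.survival_group == GROUP_SHORT]
        long_ = [f for f in self.folds if f.survival_group == GROUP_LONG]
        c_short = sum(1 for f in short if f.binary_class == CLASS_BAD)
        c_long = sum(1 for f in long_ if f.binary_class == CLASS_GOOD)
        return c_short, len(short), c_long, len(long_)

    @property
    def clear_prognosis_accuracy(self) -> float:
        """Strict accuracy: unclassifiable folds count as incorrect."""
        c1, n1, c2, n2 = self.correct_counts()
        if n1 + n2 == 0:
            raise UndefinedScoreError("no patients with clear prognosis")
        return (c1 + c2) / (n1 + n2)

    @property
    def n_unclassifiable(self) -> int:
        return sum(1 for f in self.folds if f.binary_class == UNCLASSIFIABLE)

    @property
    def classified_accuracy(self) -> float:
        """Accuracy among the clear-prognosis patients the method managed to
        classify — the quantity a study with no undefined folds reports.
        Undefined when every clear-prognosis fold was unclassifiable."""
        clear = [
            f for f in self.clear_prognosis_folds() if f.binary_class != UNCLASSIFIABLE
        ]
        if not clear:
            raise UndefinedScoreError("no classifiable clear-prognosis patients")
        correct = sum(
            1
            for f in clear
            if (f.survival_group == GROUP_SHORT and f.binary_class == CLASS_BAD)
            or (f.survival_group == GROUP_LONG and f.binary_class == CLASS_GOOD)
        )
        return correct / len(clear)


def loo_cross_validate(
    cohort: Cohort,
    candidates: Sequence[str],
    alpha: float = 0.05,
    cutoff: float = DEFAULT_BINARY_CUTOFF,
    *,
    cutoff_preset: str = "methods",
    refit: bool = True,
    model: IsirModel | None = None,
) -> LooReport:
    """Leave-one-out cross-validation of the full pipeline.

    With ``refit=True`` (default) each fold re-screens and re-weights on the
    n-1 training patients — the honest protocol, since variable selection is
    part of the estimator. ``refit=False`` keeps the weights of ``model``
    (or of a fit on the full cohort) fixed and only re-scores, for comparison.
    Folds whose training model is undefined (no significant protective
    variable) are recorded as unclassifiable, never dropped.
    """
    if len(cohort) < 4:
        raise ValidationError("loo_cross_validate: need at least 4 patients")
    groups = dict(
        zip(
            (p.patient_id for p in cohort.patients),
            survival_groups(cohort.survival_times, cohort.events),
        )
    )
    if not refit and model is None:
        model = fit_isir(
            cohort, candidates, alpha, cutoff_preset=cutoff_preset, binary_cutoff=cutoff
        )
    folds = []
    for patient in cohort.patients:
        try:
            if refit:
                fold_model = fit_isir(
                    cohort.drop(patient.patient_id),
                    candidates,
                    alpha,
                    cutoff_preset=cutoff_preset,
                    binary_cutoff=cutoff,
                )
            else:
                fold_model = model
            scored = isir_score(fold_model, patient)
        except UndefinedScoreError as exc:
            folds.append(
                LooFold(
                    patient_id=patient.patient_id,
                    survival_group=groups[patient.patient_id],
                    isir=None,
                    risk_class=UNCLASSIFIABLE,
                    binary_class=UNCLASSIFIABLE,
                    note=str(exc),
                )
            )
            continue
        folds.append(
            LooFold(
                patient_id=patient.patient_id,
                survival_group=groups[patient.patient_id],
                isir=scored.isir,
                risk_class=scored.risk_class,
                binary_class=scored.binary_class,
            )
        )
    return LooReport(folds, alpha, cutoff)
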