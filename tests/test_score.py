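import numpy as np
import pytest

from isir.cohort import PatientRecord, VariableSpec, cohort_from_arrays
from isir.errors import UndefinedScoreError, ValidationError
from isir.score import (
    IsirModel,
    WeightedVariable,
    classify_binary,
    classify_risk,
    fit_isir,
    isir_score,
    loo_cross_validate,
    scale_value,
    screen_variables,
)

TABLE_WEIGHTS = IsirModel(
    aggressive=[
        WeightedVariable("T", 0.55, 4),
        WeightedVariable("N", 0.41, 4),
        WeightedVariable("M", 0.37, 2),
    ],
    protective=[
        WeightedVariable("Gas6", 0.31, 4),
        WeightedVariable("CD68", 0.32, 4),
    ],
)


def brute_force_isir(model, patient):
    """Explicit-loop oracle for the score, independent of the implementation."""
    num = den = wsum = vsum = 0.0
    for v in model.aggressive:
        num += v.weight * patient.covariates[v.name] / v.divisor
        wsum += v.weight
    for v in model.protective:
        den += v.weight * patient.covariates[v.name] / v.divisor
        vsum += v.weight
    return (num / wsum) / (den / vsum)


class TestScaleValue:
    @pytest.mark.parametrize(
        "value, spec, expected",
        [
            (1, VariableSpec("M", (0, 1)), 0.5),
            (4, VariableSpec("T", (1, 2, 3, 4)), 1.0),
            (0, VariableSpec("N", (0, 1, 2, 3)), 0.0),
        ],
    )
    def test_divides_by_number_of_realizations(self, value, spec, expected):
        assert scale_value(value, spec) == expected

    def test_inadmissible_value_rejected(self):
        with pytest.raises(ValidationError):
            scale_value(5, VariableSpec("T", (1, 2, 3, 4)))


class TestIsirScore:
    def test_worked_low_risk_patient(self):
        p = PatientRecord("a", 10, 1, {"T": 2, "N": 0, "M": 0, "Gas6": 1, "CD68": 3})
        assert isir_score(TABLE_WEIGHTS, p).isir == pytest.approx(0.410, abs=1e-3)

    def test_worked_high_risk_patient(self):
        p = PatientRecord("b", 10, 1, {"T": 4, "N": 2, "M": 1, "Gas6": 1, "CD68": 2})
        assert isir_score(TABLE_WEIGHTS, p).isir == pytest.approx(1.875, abs=1e-3)

    def test_zero_aggressive_values_give_zero_score(self):
        model = IsirModel(
            aggressive=[WeightedVariable("N", 0.4, 4), WeightedVariable("M", 0.3, 2)],
            protective=[WeightedVariable("Gas6", 0.3, 4)],
        )
        p = PatientRecord("z", 10, 1, {"N": 0, "M": 0, "Gas6": 2})
        assert isir_score(model, p).isir == 0.0

    def test_zero_protective_side_is_undefined(self):
        model = IsirModel(
            aggressive=[WeightedVariable("T", 0.5, 4)],
            protective=[WeightedVariable("N", 0.3, 4)],
        )
        p = PatientRecord("z", 10, 1, {"T": 2, "N": 0})
        with pytest.raises(UndefinedScoreError):
            isir_score(model, p)

    def test_missing_covariate_rejected(self):
        p = PatientRecord("m", 10, 1, {"T": 2, "N": 0, "M": 0, "Gas6": 1})
        with pytest.raises(ValidationError, match="CD68"):
            isir_score(TABLE_WEIGHTS, p)

    def test_matches_brute_force_oracle_on_random_patients(
        self, rng, random_patient_factory
    ):
        for p in random_patient_factory(rng, 1000):
            assert isir_score(TABLE_WEIGHTS, p).isir == pytest.approx(
                brute_force_isir(TABLE_WEIGHTS, p), abs=1e-12
            )

    def test_monotone_in_each_covariate(self, rng, random_patient_factory):
        for p in random_patient_factory(rng, 200):
            base = isir_score(TABLE_WEIGHTS, p).isir
            for v in TABLE_WEIGHTS.aggressive:
                spec_vals = (0, 1) if v.name == "M" else (1, 2, 3, 4) if v.name == "T" else (0, 1, 2, 3)
                if p.covariates[v.name] < max(spec_vals):
                    bumped = dict(p.covariates)
                    bumped[v.name] += 1
                    up = isir_score(
                        TABLE_WEIGHTS, PatientRecord("q", 10, 1, bumped)
                    ).isir
                    assert up >= base - 1e-12
            for v in TABLE_WEIGHTS.protective:
                if p.covariates[v.name] < 4:
                    bumped = dict(p.covariates)
                    bumped[v.name] += 1
                    up = isir_score(
                        TABLE_WEIGHTS, PatientRecord("q", 10, 1, bumped)
                    ).isir
                    assert up <= base + 1e-12

    def test_weight_scale_invariance(self, rng, random_patient_factory):
        scaled = IsirModel(
            aggressive=[
                WeightedVariable(v.name, 7.3 * v.weight, v.divisor)
                for v in TABLE_WEIGHTS.aggressive
            ],
            protective=[
                WeightedVariable(v.name, 0.11 * v.weight, v.divisor)
                for v in TABLE_WEIGHTS.protective
            ],
        )
        for p in random_patient_factory(rng, 1000):
            assert isir_score(scaled, p).isir == pytest.approx(
                isir_score(TABLE_WEIGHTS, p).isir, abs=1e-12
            )


class TestClassification:
    @pytest.mark.parametrize(
        "score, preset, expected",
        [
            (0.20, "methods", "low"),
            (0.25, "methods", "low"),  # boundary included
            (0.35, "methods", "intermediate"),
            (0.5, "methods", "high"),
            (0.90, "table", "high"),
            (0.4, "table", "intermediate"),  # strict boundaries fall inward
            (0.8, "table", "intermediate"),
            (0.1, "table", "low"),
        ],
    )
    def test_three_class_presets(self, score, preset, expected):
        assert classify_risk(score, preset) == expected

    def test_negative_score_rejected(self):
        with pytest.raises(ValidationError):
            classify_risk(-0.1)

    @pytest.mark.parametrize(
        "score, expected", [(0.5, "good"), (0.51, "bad"), (0.0, "good")]
    )
    def test_binary_cutoff_boundary_is_good(self, score, expected):
        assert classify_binary(score) == expected


class TestScreeningAndFit:
    def test_staged_cohort_partition(self, staged_cohort):
        model = fit_isir(staged_cohort, ["T", "N", "M", "Gas6", "CD68"])
        assert {v.name for v in model.aggressive} == {"T", "N", "M"}
        assert {v.name for v in model.protective} == {"Gas6", "CD68"}
        assert all(v.weight > 0 for v in model.aggressive + model.protective)

    def test_perfect_anticorrelated_candidate_gets_weight_one(self, tnm_specs):
        # tie-free perfect orderings so |r_s| is exactly 1
        times = [40.0, 30.0, 20.0, 10.0]
        T = [1, 2, 3, 4]
        Gas6 = [4, 3, 2, 1]
        cohort = cohort_from_arrays(
            times, [1] * 4, {"T": T, "Gas6": Gas6}, tnm_specs[:1] + tnm_specs[3:4]
        )
        model = fit_isir(cohort, ["T", "Gas6"])
        assert model.aggressive[0].name == "T"
        assert model.aggressive[0].weight == pytest.approx(1.0, abs=1e-9)

    def test_null_cohort_raises_undefined_score(self, rng, tnm_specs):
        times = rng.uniform(1, 100, 63)
        cov = {s.name: rng.choice(s.admissible_values, 63) for s in tnm_specs}
        cohort = cohort_from_arrays(times, np.ones(63, int), cov, tnm_specs)
        screening = screen_variables(cohort, [s.name for s in tnm_specs])
        if not screening.protective:  # overwhelmingly likely under the null
            with pytest.raises(UndefinedScoreError):
                fit_isir(cohort, [s.name for s in tnm_specs])

    def test_constant_candidate_is_excluded_not_fatal(self, tnm_specs):
        times = [40.0, 30.0, 20.0, 10.0, 5.0, 2.0]
        cohort = cohort_from_arrays(
            times,
            [1] * 6,
            {"T": [1, 1, 2, 3, 4, 4], "M": [0, 0, 0, 0, 0, 0]},
            [tnm_specs[0], tnm_specs[2]],
        )
        screening = screen_variables(cohort, ["T", "M"])
        roles = {r.name: r.role for r in screening.results}
        assert roles["M"] == "excluded"

    def test_alpha_out_of_range_rejected(self, staged_cohort):
        with pytest.raises(ValidationError):
            screen_variables(staged_cohort, ["T"], alpha=1.5)


class TestLeaveOneOut:
    def test_folds_partition_the_cohort(self, staged_cohort):
        report = loo_cross_validate(staged_cohort, ["T", "N", "M", "Gas6", "CD68"])
        ids = [f.patient_id for f in report.folds]
        assert sorted(ids) == sorted(p.patient_id for p in staged_cohort.patients)
        assert len(set(ids)) == len(ids)

    def test_deterministic_across_runs(self, staged_cohort):
        cands = ["T", "N", "M", "Gas6", "CD68"]
        a = loo_cross_validate(staged_cohort, cands)
        b = loo_cross_validate(staged_cohort, cands)
        assert [(f.patient_id, f.isir, f.binary_class) for f in a.folds] == [
            (f.patient_id, f.isir, f.binary_class) for f in b.folds
        ]

    def test_perfectly_separating_cohort_fully_correct(self, staged_cohort):
        report = loo_cross_validate(staged_cohort, ["T", "N", "M", "Gas6", "CD68"])
        assert report.clear_prognosis_accuracy == 1.0
        assert report.n_unclassifiable == 0

    def test_fixed_weight_mode_skips_refitting(self, staged_cohort):
        cands = ["T", "N", "M", "Gas6", "CD68"]
        fixed = loo_cross_validate(staged_cohort, cands, refit=False)
        assert fixed.n == len(staged_cohort)
        full_model = fit_isir(staged_cohort, cands)
        for fold, patient in zip(fixed.folds, staged_cohort.patients):
            assert fold.isir == pytest.approx(
                isir_score(full_model, patient).isir, abs=1e-12
            )

    def test_too_small_cohort_rejected(self, tnm_specs):
        cohort = cohort_from_arrays(
            [5.0, 10.0, 20.0],
            [1, 1, 1],
            {"T": [1, 2, 3]},
            tnm_specs[:1],
        )
        with pytest.raises(ValidationError):
            loo_cross_validate(cohort, ["T"])
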