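# isir — correlation-weighted individual risk scoring for survival cohorts

`isir` builds and evaluates a composite prognostic score for patient cohorts
with survival follow-up and ordinal covariates — tumour stage components
(T, N, M), histology, and semi-quantitatively graded biomarker stainings such
as CD68 or Gas6 in non-small-cell lung cancer. It is aimed at biostatisticians
and translational researchers who want a transparent, correlation-based
alternative to Cox regression for integrating clinical and molecular markers
into one risk number, together with the machinery needed to judge it:
Kaplan–Meier/log-rank screening, a backward-selected proportional-hazards
comparator, ROC analysis, classification tables, and leave-one-out
cross-validation — all exercisable on calibrated synthetic cohorts.

## The score

Candidate covariates are screened by their Spearman rank correlation
*r*<sub>S</sub>(*x*, *t*) with observed survival time *t* (two-sided p < 0.05).
Significantly negatively correlated variables *x*<sub>1</sub>…*x*<sub>k₁</sub>
are *aggressive* (larger value, shorter survival); positively correlated ones
*y*<sub>1</sub>…*y*<sub>k₂</sub> are *protective*. Each variable is divided by
its number of possible realizations (2 for binary M and histology, 4 for the
graded variables), putting all of them on a common [0, 1] scale, and the
integrated score for an individual risk is the ratio of weighted averages

```
          Σᵢ wᵢ · x̃ᵢ / Σᵢ wᵢ
  ISIR = ─────────────────────,   wᵢ = |r_S(xᵢ, t)|,  vⱼ = r_S(yⱼ, t) > 0,
          Σⱼ vⱼ · ỹⱼ / Σⱼ vⱼ
```

with x̃, ỹ the scaled values. Large ISIR means the aggressive side dominates:
high predicted risk. ISIR ≤ 0.25 is low risk, ≥ 0.5 high risk (an alternative
0.4/0.8 banding is also shipped); the binary prognosis cut-off is 0.5.
The comparator is the Cox model λ(t, X) = λ₀(t)·exp(Xβ) with automatic
backward elimination at p > 0.05, classified on its linear predictor Xβ.

## Worked example

```python
from isir import SimulationConfig, fit_isir, generate_cohort, loo_cross_validate

cohort = generate_cohort(SimulationConfig(n=63, seed=11))   # NSCLC-like cohort
model = fit_isir(cohort, cohort.variable_names)              # screen + weight
report = loo_cross_validate(cohort, cohort.variable_names)   # honest LOO
```

Running `python examples/01_fit_and_score.py` prints:

```
screened 9 candidates on n=63:
  aggressive  T      weight 0.509 (scale 1/4)
  aggressive  N      weight 0.374 (scale 1/4)
  aggressive  M      weight 0.484 (scale 1/2)
  protective  CD68   weight 0.322 (scale 1/4)
  excluded    H, Gas6, Cox2, MMP2, Notch3
...
  P0004: ISIR=0.667 -> high         (bad); observed 8 mo, death
```

The weights are this cohort's Spearman correlations: stage dominates the
aggressive side, CD68 carries the protective side, and patient P0004 — high
stage, weak marker expression — scores 0.667 (> 0.5, "bad" prognosis) and
indeed died at 8 months. `examples/02_crossvalidate.py` cross-validates the
same cohort (13/19 short survivors and 14/15 long survivors correct, 79%
clear-prognosis accuracy), `examples/03_cox_comparison.py` fits the
backward-selected hazard model (retaining T and M here, rank agreement
r_s = 0.93 with ISIR), and `examples/04_synthetic_calibration.py` shows the
copula calibration behind the generator.

A thin CLI wraps the same pipeline for shell use:

```sh
isir simulate --n 63 --seed 11 --out-dir run/
isir fit      --cohort run/cohort.csv --spec run/variables.json --out-dir run/
isir crossval --cohort run/cohort.csv --spec run/variables.json --out-dir run/
```

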