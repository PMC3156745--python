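# Methods

## The score and its assumptions

The score treats individual risk as a balance between aggressive and
protective ordinal covariates. Screening, weighting and interpretation all
rest on Spearman correlation with *observed* survival time, with censoring
status deliberately ignored at this stage. That is defensible only when
censored follow-up times are long relative to the classification horizon —
the regime the method targets, where administrative censoring happens years
after the 12-month "short survival" boundary. Censoring is handled properly
where it changes the answer: Kaplan–Meier curves, the log-rank test, and the
partial-likelihood comparator.

Given screened variables, the score for a patient is the ratio of two
weighted averages of scaled covariate values (see README for the formula).
Two normalisation conventions are possible — dividing each side by its weight
sum or not. The package defaults to dividing (`IsirModel.normalize=True`):
it makes the score invariant to rescaling either side's weights, which is
what allows fixed cut-offs (0.25/0.5) to transfer across cohorts whose
correlation magnitudes differ; the unnormalised variant remains available as
a switch. The score is undefined when no protective variable passes the
screen (empty denominator) or when a patient's protective side is zero —
both conditions raise explicit errors rather than producing sentinel values.
With protective gradings coded from 1 upward the patient-level zero cannot
occur; it can for codings that include 0.

Boundary conventions follow the printed definitions exactly: the
three-class "methods" preset includes its boundaries (≤ 0.25 low, ≥ 0.5
high); the alternative "table" preset (0.4/0.8) and both Cox presets
(−6/−4.5 three-class, −5.5 binary) use strict inequalities with boundaries
falling to intermediate; binary ISIR 0.5 is "good".

## Statistical building blocks

* **Spearman correlation** uses mid-ranks for ties (heavily tied ordinal
  gradings make this essential) and the two-sided t-approximation
  t* = r·√((n−2)/(1−r²)) for p-values; an exact permutation p-value is
  available for n ≤ 9. Implementation: `scipy.stats.spearmanr`; the test
  suite checks it against an explicitly constructed Pearson-on-mid-ranks
  oracle to 1e−12.
* **Kaplan–Meier** and the **K-sample log-rank test** (hypergeometric
  variance over pooled event times, χ² on K−1 df) delegate to lifelines.
* **Cox fitting** delegates to statsmodels PHReg with Breslow tie handling
  (the SAS PHREG convention; Efron is a flag away). Backward elimination is
  authored here: refit after removing the worst Wald p-value while it
  exceeds 0.05, ties in p broken by candidate order, with an elimination
  trace in the returned model. Non-convergence (monotone likelihood,
  |β| > 50, non-finite standard errors) raises an error naming the variable.
* **AUC** is the Mann–Whitney pairwise probability with half credit for
  ties (scikit-learn), positives being the ≤12-month group and higher
  scores predicting them; the intermediate-survival group is excluded from
  ROC and pooled accuracy but retained in three-class tables.
* **Survival groups**: ≤ 12 months short, ≥ 60 long, boundaries included on
  both sides. Censored patients are grouped by observed follow-up — someone
  censored beyond 60 months has survived 60 months; a censoring time inside
  (12, 60) leaves the truth unknown and the patient sits in "mid".

## Leave-one-out cross-validation

Each fold re-screens and re-weights on the n−1 training patients (variable
selection is part of the estimator; freezing it would leak information). A
`refit=False` mode scores with fixed full-cohort weights for comparison. A
fold whose training set yields no significant protective variable cannot
form a score; it is recorded as *unclassifiable*, never dropped. The report
exposes two accuracy summaries over the clear-prognosis (≤12 / ≥60 month)
patients: `clear_prognosis_accuracy` counts unclassifiable folds as
incorrect; `classified_accuracy` conditions on a score having formed. The
second is the quantity comparable to a study in which every cross-validated
patient received a classification; the first quantifies how often the method
abstains. Both are reported wherever one is.

## The synthetic-cohort generator

The generator emulates a ~63-patient resected-NSCLC cohort: ordinal margins
taken from the pooled descriptive counts of such a cohort (e.g. metastases
in 10/63, CD68 split 3/60 between grades II and III), covariate–survival
Spearman targets of −0.55/−0.41/−0.37 for T/N/M and +0.31/+0.32 for
Gas6/CD68, no real association for histology, Cox2, MMP2 and Notch3, and
roughly a fifth of patients administratively censored late in follow-up.

Construction is a one-factor Gaussian copula: a latent health factor Z₀
drives survival through a Weibull proportional-hazards transform
T = (E·exp(b·Z₀)/λ₀)^(1/k), E ~ Exp(1), and each covariate thresholds its own
latent normal (correlation ρ with Z₀) into its marginal categories. Both
discretisation and the exponential draw attenuate rank correlation, so each
ρ is found by pilot-simulation inversion (common-random-number bisection on
a 100 000-draw pilot, cached); a target above the margin-limited ceiling
raises an error reporting the attainable bound. The one-factor structure
keeps the implied latent correlation matrix positive definite by
construction and is checked anyway.

Default parameters, chosen once: factor coefficient b = 3.0 — the extreme
CD68 margin caps the attainable |r_S| near 0.35 and smaller coefficients
push the 0.32 target above that ceiling; Weibull shape k = 2.0 and baseline
median 26 months — with b fixed by the ceiling, an exponential (k = 1) would
force a log-survival spread of ~3.3 and grossly overweight both tails,
whereas k = 2 gives the spread (~1.6) that reproduces the intended
short/mid/long prognosis margins (pilot: 0.34/0.42/0.25 of patients) and a
censored fraction of ~0.22 under the uniform 54–101-month censoring window.
The factor model is a deliberate simplification: real stage components are
correlated with each other beyond what one factor induces, margins are
estimates, and grading noise between observers is absent — so passing
recovery tests shows the pipeline is consistent under its own assumptions,
not that any clinical cohort satisfies them.

At the default n = 63 the screen's power for the protective targets
(|r| ≈ 0.31 vs a critical value ≈ 0.25) is modest, so a minority of
replicate cohorts yield no significant protective variable at all; this is
a property of the study conditions, reported by the replication studies as
undefined-cohort and unclassifiable-fold rates rather than hidden.

## Replication studies and problem sizes

`isir.study` drives the simulation studies the acceptance script reports:
partition/weight recovery over 100 cohorts of n = 5000 (a null covariate is
expected to slip past an α = 0.05 screen in ~5% of cohorts at any n, so
recovery is judged on the five signal variables landing on their correct
sides within ±0.05 of target weight); Cox log-hazard-ratio consistency as
the mean of 10 two-group exponential fits at n = 500 (single-fit sampling
error ~0.09 would otherwise dominate); and mean LOO accuracy over 200
cohorts at the original n = 63. These sizes keep the full suite and the
acceptance script around a minute each on one CPU while holding Monte-Carlo
error on the reported rates to a point or two.

## Known limitations

* The score presumes at least one protective variable exists; cohorts
  without one get an error, not a degenerate score.
* Correlated predictors are not de-duplicated — closely linked variables
  with similar roles are effectively double-counted, a known property of
  correlation-weighted composites.
* Spearman screening ignores censoring; with heavy or early censoring the
  screen is biased and the method should not be used unmodified.
* The generator's calibration is Monte-Carlo (±~0.005 at the default pilot
  size) and its caching keys on the full study conditions; changing margins
  or hazard parameters triggers recalibration.
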