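# Methods

## Scoring rules and conventions

The component rules are deterministic lookups; the only places where a
published tabulation leaves room are boundaries and units, resolved as
follows:

* **pH bands.** The acidemia bands are taken contiguous and inclusive at
  both printed edges: pH ∈ [7.20, 7.35] → 1 point, pH < 7.20 → 2, pH > 7.35
  → 0. This is the only assignment that covers the line without overlap.
* **Albumin unit.** Thresholds and values are in g/dL. Printed score tables
  sometimes carry an mg/dl label on the albumin row; every clinically
  plausible serum albumin (1–6) and the threshold 3.0 are on the g/dL scale,
  so the label is treated as a typo. The schema documents this loudly.
* **Arrest rule.** SBP ≤ 60 mmHg is inclusive; cardiac arrest dominates, so
  a patient in arrest scores 2 points regardless of any recorded pressure
  (by convention the simulator writes SBP = 0 for arrest patients). The SBP
  used is the arrival value.
* **Missing predictors are a hard error at scoring time**
  (`UnresolvedPredictorError` naming the field). Resolution is strictly the
  imputation stage's job, which keeps the pipeline ordering auditable.

## Probability model

The score-to-probability map is logistic,
`P(death) = expit(intercept + slope_per_point · total)`, optionally replaced
by an explicit 10-entry per-score lookup. The coefficients of the original
derivation were published only in supplementary material that is not openly
available, so they are **configuration**, not constants. The package's
reference fit — `reference_probability_model()` — regresses outcome on total
score over the exact-table synthetic cohort and yields intercept ≈ −2.024,
slope ≈ 0.228 per point (probabilities 0.117 at score 0 rising to 0.508 at
score 9). It is a clearly labelled stand-in: any analysis against real data
should substitute the true coefficients via `RunConfig` or
`ScoreProbabilityModel`.

## Validation metrics

* **C statistic**: delegated to a rank-based AUC routine; equals
  (concordant + ½ tied) / (all death–survivor pairs). The CI is a percentile
  bootstrap over patients, 2000 resamples by default, seeded; resamples that
  draw a single outcome class carry no pairs and are skipped. A DeLong
  closed-form variance is available as an option. The bootstrap was chosen
  as the default because it is assumption-light and bit-reproducible.
* **Calibration intercept** uses the offset convention
  ("calibration-in-the-large"): an intercept-only logistic model with
  logit(p) as fixed offset; the **slope** comes from the free refit of
  outcome on logit(p). Perfect separation is reported as non-convergence
  rather than returning an unstable estimate.
* **Nagelkerke R²** treats the predictions as externally supplied — no
  parameters are re-estimated — and rescales the Cox–Snell R² by its
  maximum. Probabilities are clamped to [1e−12, 1 − 1e−12] before any
  log-likelihood (a warning is emitted when clamping bites).
* **Grouped calibration** reports per band n, deaths, observed rate, and
  the mean predicted probability with a normal-approximation CI of the mean
  (matching the symmetric intervals conventionally reported). Empty bands
  are kept as n = 0 rows, not dropped.
* **Smoothed calibration curve**: tricube-weighted local *linear*
  regression (LOWESS with zero robustness iterations), default fraction
  0.75, evaluated at each distinct predicted value — for a score model that
  is one point per attainable score.

## Decision-curve analysis

Net benefit is `TP/n − (FP/n)·p_t/(1−p_t)` with the tie-at-threshold
classified positive (documented because boundary patients flip TP/FP
counts). The default threshold grid is 0.01–0.60 in steps of 0.01, the
clinically relevant range for mortality decisions; it is configurable. The
age-only and temperature-only comparators are univariable logistic refits
on the evaluation cohort itself, giving each comparator its best-calibrated
probability scale; a constant covariate degenerates the fit and that
strategy is skipped with a warning. Treat-all and treat-none are computed
through the same thresholding code and therefore satisfy their closed forms
(`prevalence − (1−prevalence)·p_t/(1−p_t)` and 0) identically.

## Missing-data resolution

* **Albumin from total calcium.** Serum albumin and total calcium are
  linearly related; the default affine conversion inverts the Payne
  correction (0.8 mg/dL calcium per 1 g/dL albumin anchored at
  Ca 9.5 ↔ Alb 4.0): `albumin = 1.25·Ca − 7.875` g/dL, clipped to
  [1.0, 6.0]. The (intercept, slope) are configuration so that alternative
  estimating equations can be swept in sensitivity analyses.
* **Worst-case scenarios** bound the albumin component's influence: every
  unmeasured-albumin patient receives the full point (high) or none (low).
  Since the component is worth exactly one point, the two scenarios bracket
  every patient's total score, and hence band assignment, patient by
  patient.
* **Iterative imputation** of remaining numeric predictors uses chained
  extra-trees regressions cycled field-wise (10 cycles maximum, tolerance
  1e-3), seeded and deterministic. This is a generic nonparametric chained
  imputer with the same contract as forest-based multiple-imputation tools:
  observed cells are restored verbatim after imputation, binary indicators
  are rounded back to {0, 1}, and an all-missing column is an error naming
  the column. Multiple-imputation pooling across m completed datasets is
  out of scope; the pipeline consumes a single completed dataset.

## Synthetic cohorts

`generate_cohort` emulates a nationwide hypothermia registry's published
marginals: age 79 [68–87], SBP 117 [87–144], pH 7.29 [7.18–7.35], estimated
albumin 3.54 [3.23–3.77], body temperature 30.9 [28.2–33.4] truncated at
the 35 °C inclusion ceiling, 54.9% male, 22% ADL disturbance, 8.9% cardiac
arrest. Continuous marginals use a **two-piece (split) normal** whose lower
and upper halves are scaled so the 25th/50th/75th percentiles hit the
published targets exactly; this family was chosen over two-parameter skew
families because the age marginal's quartile asymmetry lies outside the
skew-normal's attainable range. Truncation (and zeroing SBP for arrest
patients) shifts the realised SBP and temperature quartiles slightly below
target; age, pH and albumin reproduce their targets within ±2% at large n.
Calcium is simulated on the scale implied by the albumin targets through the
configured conversion, so the *estimated* albumin reproduces its published
marginal. Outcomes are Bernoulli draws from a configurable logistic model
applied to each patient's true score (defaulting to the reference fit).

Covariates are otherwise generated **independently** — the registry's joint
distribution is unpublished. Passing tests on these cohorts therefore
demonstrate the correctness of the pipeline's computations, not the
transportability of the score to real data, where predictor correlations
(e.g. age × ADL) and measurement error will differ.

`generate_exact_table_cohort` is deterministic: per band it spreads patients
evenly over the band's attainable scores (largest-remainder apportionment),
assigns the band's published deaths to its first patients, and builds
covariates from per-score templates that are re-verified to round-trip
through the scorer at assembly time. Body temperature in this cohort cycles
deterministically over 28–35 °C so a temperature comparator is never
degenerate.

## Problem sizes used in tests

Marginal-fidelity checks use n = 100 000 draws; calibration
identity/distortion recovery uses n = 5000–8000 with fixed seeds and
Monte-Carlo tolerances of about ±0.1 on slope and intercept; imputation
benchmarks use n = 1200 with 10% injected missingness; bootstrap CIs in
pipeline tests use reduced resample counts (20–300) while the package
default remains 2000. These sizes keep every statistical check well inside
its tolerance while the full suite runs in about a minute.

## Known limitations

* The reference probability coefficients are a stand-in fit on synthetic
  data, so probability-dependent outputs (predicted band means, Brier,
  Nagelkerke R², DCA model curve) are model-configuration-dependent until
  true coefficients are supplied. Rank-based outputs (C statistic on the
  score) are unaffected as long as the map is monotone.
* Whether a published C statistic was computed on the integer score or on
  model probabilities is rank-equivalent under a monotone map, but the
  package computes it on whatever predictions it is given — callers choose.
* The simulator's independence assumption understates realistic predictor
  correlation; the exact-table mode fixes only band totals, with a uniform
  score mix within bands (the published table reports band totals only).
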