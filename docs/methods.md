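# Methods

## The problem and the estimand

Office and out-of-office blood pressure disagree in a clinically important
minority of adults. With office hypertension defined as mean office
SBP/DBP ≥ 130/80 mm Hg and out-of-office hypertension as mean awake
ambulatory SBP/DBP ≥ 130/80 mm Hg, every person falls into one of four
phenotypes (sustained normotension, masked hypertension, white coat
hypertension, sustained hypertension; "controlled/uncontrolled" variants of
the same four when on antihypertensive medication). The package's estimand
chain is: (1) a person-level prediction of mean awake BP from office data
and covariates; (2) a tri-state triage decision derived from that
prediction; (3) cohort- and population-level summaries of the decision
rule's burden and error.

## Difference model

The prediction target is the *difference* between mean awake BP and the
first office reading, modelled linearly on covariate terms; predicted awake
BP adds the predicted difference back to the first office reading.
Modelling the difference rather than the level hard-codes the strong prior
that office BP carries most of the signal, and lets a negative
first-office-reading coefficient express regression to the mean. Terms are
main effects, squares and pairwise products of: age (years), sex (male = 1),
BMI (kg/m²), first office SBP/DBP (mm Hg), and 0/1 indicators for diabetes,
CKD, CVD history, self-reported hypertension, antihypertensive use, smoking
(former/current vs never), any alcohol use, and high-school education.
Coefficients are on natural scales; no standardization. Models serialize to
JSON (terms, coefficients, provenance) so externally published coefficient
sets can be loaded and evaluated by the same engine — no coefficients are
hard-coded in the package.

## Development procedure

* **Selection CV.** Participants are partitioned into k = 10 seeded folds
  (ids sorted before shuffling, so row order is irrelevant). On each
  9-fold training set, multistep backward elimination removes one
  non-prespecified term at a time — the one with the largest Wald p-value
  above α = 0.05 — refitting after each removal. Intercept, age, sex and the
  first office reading of the outcome are prespecified and never eligible.
  Under the hierarchy rule (default on) a main effect is ineligible while
  any surviving square/product term uses its covariate, so derived terms die
  before their parents become removable.
* **Majority vote.** A candidate enters the final model when selected in
  more than half of the folds (≥ 6 of 10; a term selected in exactly 5 of
  10 is excluded). Final coefficients are a full-data OLS refit of the
  selected terms.
* **Internal validation.** A second 10-fold CV with an independent seeded
  partition refits the *fixed* final term set per training split and
  predicts the held-out fold, giving exactly one honest prediction per
  participant.

The per-term p-value criterion, one-at-a-time removal, α = 0.05 and the
unstratified fold assignment are this package's concrete choices for a
procedure whose fine detail is conventionally under-specified; all four are
exposed in `DevelopmentConfig`. One numerical guard: in a (near-)perfect
fit the residual variance is ~0 and Wald p-values are noise, so a term
whose standardized contribution is numerically zero (|β|·sd(x) < 1e-6 ·
sd(y)) is treated as removable. This makes the zero-noise limit recover
the true support exactly without affecting noisy fits.

## Validation metrics

Mean difference (predicted − observed), mean absolute difference, Pearson
r, and AUROC for discriminating awake BP ≥ 130 (SBP) / ≥ 80 (DBP) mm Hg.
AUROC is pairwise concordance — the probability a random hypertensive
outscores a random normotensive, ties counted ½ — computed via midranks
(Mann–Whitney); a brute-force pair loop serves as the oracle in tests.
Sensitivity counts predicted ≥ threshold as test-positive (closed lower
bound, matching the ≥ 130/≥ 80 definitions).

Confidence intervals are bias-corrected and accelerated (BCa) bootstrap,
default 500 replicates: z₀ from the share of replicates below the point
estimate (half-weight on ties, clamped away from 0/1), acceleration from
leave-one-out jackknife skewness, adjusted-percentile endpoints. With
z₀ = a = 0 the construction reduces to the plain percentile interval, which
tests assert directly; `scipy.stats.bootstrap(method="BCa")` is an
independent cross-check, not the implementation. Resampling is always by
participant, never by reading. Degenerate statistics return a zero-width
interval with a warning.

## Referral-range optimization

Windows are half-open [L, H) on a 5 mm Hg grid; the display "120–134"
means [120, 135). Decision precedence is above > within > below: e.g. SBP
above its window with DBP inside → assume hypertension. This resolves the
overlap in an "either … within / either … above" rule in the escalating,
clinically conservative direction and makes the three states a partition.

Misclassification among the not-referred counts both error directions —
assumed normotensive but observed hypertensive, and assumed hypertensive
but observed normotensive — at the awake 130/80 thresholds, pooled over
both medication strata (per-stratum optimization is out of scope; the
constraint is evaluated on the whole cohort). When nobody is unreferred the
proportion is defined as 0. The optimizer evaluates all 441 pairs,
keeps those with misclassification < 0.20, and minimizes the referred
proportion; ties break by lower misclassification, then smaller total
window width, then lower SBP then DBP low edge — deterministic and
audit-friendly (the full grid is always emitted). If no pair is feasible
the minimal-misclassification pair is returned flagged infeasible.

The office-band comparator applies the same tri-state logic to mean office
BP. Default bands are [120, 160) / [75, 100) mm Hg for both medication
strata: the upper portion mirrors a guideline referral range of
130–159/80–99 mm Hg, and the lower edge extends below 130/80 so
office-normotensive people can still be screened for masked hypertension.
The bands are configuration, not logic.

## Survey projection

Survey persons carry office readings, covariates, a sampling weight and
stratum/PSU design labels — no awake BP, which is exactly the deployment
setting. Referred proportions are weight-averaged per analysis stratum
(medication use × office hypertension status); population counts are sums
of weights. Interval estimation resamples PSUs with replacement within
design strata (replicate bootstrap, percentile endpoints). Full
Taylor-linearization variance for complex multistage designs is a
non-goal; the replicate bootstrap is adequate for the synthetic designs the
generator produces.

## Synthetic data generator

The generator emulates the structure of a pooled US ABPM cohort:

* **Covariate marginals** (defaults): age ~ N(52.0, 11.9²) clipped to
  [20, 90]; BMI ~ N(29.8, 6.5²); male 38%, Black race 54%, diabetes 15.7%,
  CKD 10%, CVD history 5.6%, self-reported hypertension 35%, high-school
  degree 89.7%, any alcohol 66.7%, smoking never/former/current
  66/23.3/10.7%, antihypertensive use 31%. Binary comorbidities are drawn
  independently — real comorbidity correlations are *not* simulated.
* **Office readings.** A latent first office reading depends linearly on
  age, BMI and treatment status plus normal residual, calibrated so the
  defaults give first-reading mean (SD) ≈ 121.8 (16.5) / 75.3 (9.8) mm Hg.
  Later readings add within-visit noise (SD 6.7/4.7 mm Hg) and a linear
  drift whose endpoint mean is the configured last-minus-first change
  (−0.3/−0.2 mm Hg). Three readings per visit by default.
* **Awake BP.** The true awake mean is first office reading + β·x +
  N(0, σ), with default β: SBP intercept 39.7, first office SBP −0.35,
  age 0.05, male 1.5, BMI 0.2, antihypertensive use −3.0, diabetes 1.5
  (DBP analogously), and σ = 8/6 mm Hg. These defaults put the awake mean
  near 127.3/78.5 mm Hg with SD ≈ 13.5/9 and make two non-prespecified
  candidates (BMI, antihypertensive use) carry standardized effects
  ≥ 0.15 — recoverable signal — while the remaining candidates are true
  nulls. The exact coefficient values are this package's calibration; no
  published coefficient set was available to copy, and the office–awake
  residual SD of real cohorts is approximated, not known.
* **Awake readings** (default 30 per person, SD 12/9 mm Hg) scatter around
  the true mean with their sample mean pinned to it exactly; a
  redistribution pass keeps readings inside the plausibility window
  ([60, 260] SBP, [30, 160] DBP) without moving the row mean. This makes
  reading-level and mean-level pipelines agree and the zero-noise limit
  exact.
* **Survey samples** reuse the covariate and office machinery (ages
  truncated at 20, no awake data) and add weights: uniform, or a
  stratum → weight mapping with uniform stratum allocation and 10 PSUs per
  stratum.

All randomness flows from one master seed through named substreams
(covariates, office, awake-noise, awake-readings, survey, per-outcome fold
partitions), so any stage can be replayed in isolation and the end-to-end
pipeline is byte-reproducible.

**What passing tests on this generator do and do not show.** The generator
is exactly linear with homoscedastic Gaussian noise and independent
covariates, so it validates the *machinery* — selection consistency,
unbiased internal validation, constraint compliance, determinism — under
correct specification. It does not probe misspecification, heteroscedastic
or heavy-tailed awake variability, correlated comorbidities, cohort
heterogeneity, or measurement-device error; performance numbers on it
(e.g. AUROC ≈ 0.89, optimal windows narrower than on real cohorts) are
properties of the synthetic conditions, not forecasts for real data.

## Problem sizes and numerical choices

Default study scale is n = 3058 (cohort) and 10 974 (survey); the test
suite and the acceptance script use n = 3000 cohorts, a 400-person smoke
survey and reduced bootstrap replicates where full replication adds nothing
to the property under test — choices the package makes to keep the default
developer loop fast. BP values in emitted artifacts are serialized at one
decimal; internal computation is full precision. Threshold comparisons use
≥ with no pre-rounding. Rank deficiency in any fit names the collinear
terms instead of silently pseudo-inverting.

## Known limitations

* The candidate-term list and the generator's true coefficients are
  calibrated stand-ins, configurable but not transcriptions of any
  published model.
* The ≥ 10-awake-readings completeness filter is applied per reading list
  as supplied; SBP/DBP availability is treated jointly.
* Phenotype display strings cover the treated/untreated naming convention
  but no alternative guideline thresholds have been separately validated
  (thresholds are configurable).
* Home BP (as opposed to ambulatory) prediction is out of scope.
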