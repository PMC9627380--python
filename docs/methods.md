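# Methods

## The scoring model

The model is a linear point score over seven admission predictors of poor
14-day prognosis after traumatic brain injury: age, dominant damaged lobe,
GCS, APOE ε4 carrier status, serum CRP, serum IL-8 and the Marshall CT
class. Each predictor contributes an integer number of points determined
by a severity bin (see the table in the README); the per-predictor point
values are taken as fixed — the package deliberately does not re-derive
them from data, since they were the product of a manual expert-calibration
process. The achievable total ranges over [10, 33] and a patient is
predicted *poor* when the total strictly exceeds the decision threshold
(default 23.5).

**Boundary conventions.** The published bin labels abut ("10–15" next to
"≥15"). All numeric bins are implemented left-closed, `[lo, hi)`, against
the next bin's lower edge, so a value exactly on an abutting edge takes the
higher-severity bin: CRP 15 → 5 points, IL-8 10 → 2 and 20 → 4, age 60 →
6, GCS 9 → 3 and 13 → 1. This is deterministic, makes the bins provably
exhaustive and non-overlapping over each predictor's domain (age 15–75,
GCS 3–15, labs ≥ 0 — checked by a sweep test), and is consistent with the
documented worked example (CRP 14.2 → 3 points). Classification at exactly
the threshold is *good* ("poor" requires strictly greater); with the
non-integer default 23.5 the rule only matters for user-supplied integer
thresholds.

**The six- vs seven-predictor total.** The published worked example sums
six predictors (19 points) while the example patient's GCS of 8 would add
6 more (25). The scoring API defaults to all seven predictors — the model
as specified includes a GCS row — and exposes the predictor subset as an
argument so the six-predictor sum is reproducible; the package takes no
position on which total the original authors intended for classification.

Grading rules are data, not code: the default scheme ships as
`eppm/data/default_rules.yaml` and alternative point schemes load through
the same path, so rule variants can be evaluated without code changes.

## Predictor screening

Univariate stage, per variable, comparing the poor and good outcome
groups:

- *Continuous* (serum analytes): Student's t-test if both groups pass a
  Shapiro–Wilk normality gate at α_norm = 0.05, otherwise the two-sided
  Mann–Whitney U. Variance homogeneity is checked with Levene's test; a
  normal-but-heteroscedastic pair uses Welch's t rather than falling back
  to the rank test (the least destructive reading of "t-test with a
  homogeneity check"). A zero-variance group counts as non-normal by
  convention. Group summaries are reported as mean ± SD.
- *Categorical*: Pearson χ² without continuity correction (matching the
  convention of the standard clinical-statistics packages); when any
  expected count is below 5 a 2×2 table switches to Fisher's exact test
  and a larger table keeps χ² with an explicit warning.

α = 0.05 throughout; no multiple-testing correction is applied across the
univariate screen (deliberately mirroring common clinical practice — a
documented limitation, not an oversight).

Multivariate stage: all univariate-selected candidates enter one
maximum-likelihood logistic regression of poor outcome. Multi-level
predictors are coded **ordinally** — equally spaced integer levels in
increasing severity order — so each reported odds ratio is per one-level
severity increase. This matches reporting a single OR per multi-level
predictor; dummy coding is the obvious alternative and would report one OR
per non-reference level instead. The severity orders are: age ≤45 < 46–59
< ≥60; GCS 13–15 < 9–12 < ≤8; CRP <10 < 10–15 < ≥15; IL-8 <10 < 10–20 <
≥20; Marshall I < … < VI; damaged area parietal < occipital < temporal <
frontal (fixed by the observed poor-prognosis rates, since parietal and
occipital carry equal score points). Perfect separation raises an explicit
error rather than returning a huge OR, and non-convergence raises with
iteration diagnostics. Predictors with Wald *p* < α in both stages are the
selected independent risk factors.

## Evaluation

ROC thresholds are the midpoints between consecutive distinct scores plus
sentinels at (min − 0.5) and (max + 0.5), so the (sens 1, spec 0) and
(sens 0, spec 1) endpoints always exist. The AUC is the trapezoidal area,
which for this threshold family equals the tie-adjusted Mann–Whitney
concordance (ties between a poor and a good score count ½ — the two are
asserted equal to 1e-12 in the tests against an exhaustive pair-counting
oracle). The 95% CI uses the Hanley–McNeil standard error with a normal
approximation, chosen as the standard closed-form, testable option. The
Youden-optimal threshold maximizes J = sensitivity + specificity − 1 with
ties broken toward higher specificity, then the higher threshold (so the
degenerate all-ties curve returns the above-maximum sentinel).

`evaluate_model` freezes the threshold supplied by the caller — chosen on
training data — before touching the validation and testing sets; their
metrics never depend on re-optimizing against their own labels. The
training set's Youden threshold is reported alongside for reference.

## Synthetic cohorts

No patient-level data exist for this model, so the generator emulates the
published outcome-conditional structure of the 168-patient training
cohort: outcome ~ Bernoulli(78/168); each categorical predictor drawn from
its outcome-conditional category frequencies; age and GCS then drawn
uniformly inside the sampled bin (age on 15–45 / 46–59 / 60–75, GCS on
3–8 / 9–12 / 13–15); each serum analyte drawn from its outcome-conditional
normal (e.g. CRP poor 14.20 ± 5.73, good 11.97 ± 3.84 mg/L), truncated at
zero by resampling. Non-informative covariates — sex, injury mechanism,
smoking/alcohol/hypertension/diabetes — are drawn outcome-independently at
their observed marginal frequencies so the screening pipeline has true
negatives to reject. One seeded NumPy generator drives a cohort;
regeneration with the same seed is bit-identical, and reports embed the
seed plus a hash of the distribution parameters.

`poor_prevalence` accepts the closed interval [0, 1]: setting it to 1
draws a purely poor-prognosis subcohort, which is how the calibration
checks obtain conditional samples directly.

What the generator does **not** emulate, hence what passing tests do not
show about real data:

- Predictors are **conditionally independent given outcome**. Only
  per-outcome marginals are published, so no correlation structure is
  recoverable; real predictors (GCS, Marshall class, inflammatory markers)
  are correlated, which typically *lowers* a joint model's incremental
  ORs. Results on synthetic cohorts bound what the marginal structure
  alone implies, nothing more. (A Gaussian-copula hook would be the
  natural extension; it is deliberately not implemented rather than
  shipped untestable.)
- CRP and IL-8 are generated from their conditional normals and then
  binned by the scoring rules; the implied binned frequencies only
  approximate the separately published binned counts (the two published
  summaries are not exactly compatible with any single normal model).
  The continuous parameters are taken as authoritative; `summarize_cohort`
  lets the residual discrepancy be inspected, not "fixed".
- Zero-truncation is exact resampling, so an analyte whose mean sits only
  a few SDs above zero (procalcitonin: 0.62 ± 0.41) has a slightly higher
  true mean than its configured one (~+0.05); the recovery tests compare
  against the exact truncated-normal moments. CRP and IL-8 are ≥2.5 SD
  above zero (shift ≤ 0.11, well inside the ±0.3 recovery tolerance).

`generate_null_cohort` keeps the marginal structure but conditions every
predictor on an independent dummy outcome, so the pooled mixture is
preserved and the true AUC of any score is 0.5 — the null for calibration
tests.

## Numerical and design choices

- Problem sizes: the test suite uses cohorts of 60–10,000 and Monte-Carlo
  batches of 200–1,000 replicates; parameter-recovery checks run at
  n = 5,000 (logistic) and n = 10,000 (generator), sizes at which sampling
  error is small against the asserted tolerances.
- Logistic recovery is asserted as a *bias* property (mean estimate over
  replicates within 10% of truth on the OR scale) plus ≈95% CI coverage;
  a per-replicate 10% bound would be violated by ordinary sampling error
  at these sizes even for a correct estimator.
- Monte-Carlo assertions use ±2–3 binomial SEs around the nominal rate.
- Random splitting uses a seeded uniform permutation; how the original
  study handled its randomization is unknown, and `split_cohort` makes no
  claim to reproduce that split — only the set sizes.
- Invalid CSV rows are collected into a rejects report with row indices
  and reasons; a run aborts only under `strict` mode. Silent dropping is
  never done.
- The command-line interface (`eppm simulate|split|screen|score|evaluate|run`)
  is a thin layer over the library; JSON for machine reports, CSV for
  per-patient outputs, one INFO log line per stage.

## Known limitations

- The published cohort-specific performance figures (training AUC 0.881,
  validation 0.830, testing 0.777, and the associated accuracy/sensitivity/
  specificity triples and multivariate ORs) depend on the unavailable
  patient-level data and are not reproduction targets; the package instead
  verifies the properties that are checkable — exact scoring arithmetic,
  statistical calibration, estimator consistency, and that the score's
  discrimination on structurally faithful synthetic cohorts clears the
  0.60 adequacy bound (typically landing near 0.85 at n = 300).
- Ordinal coding of multi-level predictors is a modeling choice; the
  original analysis may have used dummy coding.
- No imputation: records with missing predictor values are rejected or
  raise, by design.
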