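# eppm — early-prognosis prediction for traumatic brain injury

`eppm` implements a point-based clinical risk score for predicting the
**14-day (early) prognosis of traumatic brain injury (TBI) patients** from
variables available at admission, together with the statistical pipeline
used to build and evaluate such a score. It is aimed at biostatisticians
and clinical-methods researchers who want a tested, reproducible reference
implementation of a point-scoring prognostic model of the IMPACT/CRASH
family — scoring, predictor screening, ROC evaluation and cohort
simulation — without access to patient data.

## The model

Seven admission predictors each map to an integer number of points:

| Predictor              | 0    | 1     | 2                  | 3     | 4       | 5     | 6    |
|------------------------|------|-------|--------------------|-------|---------|-------|------|
| Age (years)            |      |       |                    |       | ≤45     | 46–59 | ≥60  |
| Damaged area           |      |       | parietal/occipital | temporal | frontal |    |      |
| GCS score              |      | 13–15 |                    | 9–12  |         |       | ≤8   |
| APOE ε4 carrier        | no   |       | yes                |       |         |       |      |
| CRP (mg/L)             |      |       | <10                | 10–15 |         | ≥15   |      |
| IL-8 (pg/mL)           | <10  |       | 10–20              |       | ≥20     |       |      |
| Marshall CT class      |      | I/II  |                    |       | III/IV  |       | V/VI |

The total score `S = Σᵢ pointsᵢ` ranges over `[10, 33]`; prognosis is
classified **poor** when `S > τ` with the default decision threshold
`τ = 23.5` (so poor ⇔ `S ≥ 24` for integer totals). Numeric bins are
left-closed, so a value on an abutting edge takes the higher-severity bin
(CRP 15 → 5 points, IL-8 20 → 4 points, age 60 → 6 points).

Around the score, the package provides:

- **screening** (`eppm.screening`) — the predictor-selection pipeline:
  Shapiro–Wilk-gated Student's *t* / Mann–Whitney comparisons for
  continuous variables, Pearson χ² / Fisher's exact tests for categorical
  ones, then joint multivariate logistic regression with severity-ordinal
  coding; predictors with Wald *p* < α in both stages are retained.
- **evaluation** (`eppm.evaluation`) — ROC curves swept at score midpoints,
  trapezoidal AUC (≡ tie-adjusted concordance `P(S_poor > S_good)` + ½
  ties) with a Hanley–McNeil 95% CI, the Youden-optimal threshold
  (max `J = sens + spec − 1`), and accuracy/sensitivity/specificity at a
  frozen threshold ("positive" = poor prognosis).
- **simulation** (`eppm.simulate`) — a synthetic cohort generator whose
  defaults reproduce the published outcome-conditional structure of the
  168-patient training cohort (poor-outcome prevalence 78/168, per-outcome
  category frequencies, per-outcome lab means ± SD such as CRP
  14.20 ± 5.73 vs 11.97 ± 3.84 mg/L), plus a signal-free null variant.
- **cohort IO** (`eppm.cohort`) — validated CSV reading/writing and the
  seeded 168/300/100/64 split into training part 1/part 2, validation and
  testing sets.

## Worked example

```python
from eppm import PatientRecord, score_patient, classify

patient = PatientRecord(
    patient_id="example", age=46, sex="male", mechanism="traffic",
    damaged_area="temporal", gcs=8, apoe_e4_carrier=True,
    crp=14.2, il8=15.20, marshall="III",
)
bd = score_patient(patient)
print(bd.points)
print(bd.total, classify(bd.total))
```

prints

```
{'age': 5, 'damaged_area': 3, 'gcs': 6, 'apoe_e4_carrier': 2, 'crp': 3, 'il8': 2, 'marshall': 4}
25 poor
```

Age 46 falls in the 46–59 bin (5 points), the temporal lobe scores 3,
GCS 8 is severe (6), ε4 carriage adds 2, CRP 14.2 mg/L sits in 10–15 (3),
IL-8 15.2 pg/mL in 10–20 (2), and Marshall class III scores 4; the total
25 exceeds the 23.5 threshold, so the model predicts a poor early
prognosis. (Over the six predictors excluding GCS the same patient sums to
5 + 3 + 2 + 3 + 2 + 4 = 19.)

The full pipeline on a simulated 632-patient cohort:

```sh
eppm run --outdir out --seed 7
```

```
EPPM pipeline run (seed=7, alpha=0.05, threshold=23.5)
cohort n=632; split part1/part2/validation/testing = (168, 300, 100, 64)
screening (on training_part1) selected: age, damaged_area, gcs, marshall
train: AUC 0.849 (0.803-0.895), accuracy 76.7%, sensitivity 72.9%, specificity 79.5%
validation: AUC 0.811 (0.725-0.897), accuracy 74.0%, sensitivity 68.8%, specificity 78.8%
testing: AUC 0.853 (0.754-0.952), accuracy 75.0%, sensitivity 71.4%, specificity 77.8%
```

Screening runs on training part 1 (n=168); the score is evaluated on
part 2 and the held-out sets at the frozen threshold. `out/` contains the
cohort and per-set CSVs, `screening.json`, per-patient `scores.csv`,
`eval.json` (with ROC points and the Youden threshold of the training
curve) and `summary.txt`. Subcommands `simulate`, `split`, `screen`,
`score` and `evaluate` expose the stages individually; all reports embed
the seed and a configuration hash, so a re-run with the same seed is
byte-identical.

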