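# ddxeval

Penalty-weighted evaluation of differential-diagnosis lists against a
committee-adjudicated reference diagnosis.

## The problem

When several diagnosticians — physician groups, allied professionals, or
an AI system — each propose a differential diagnosis for the same set of
referred patients, plain accuracy measures reward over-inclusive lists:
naming every plausible cause guarantees that the eventual final diagnosis
is "included".  `ddxeval` implements an evaluation framework for exactly
this setting, built around syncope referral cohorts where a
multidisciplinary committee establishes the reference (final) diagnosis
after structured follow-up.  It is aimed at researchers comparing human
and AI diagnostic decision-making on list-valued outputs.

## The statistics

For rater *r* and case *c*, let the differential be an ordered,
duplicate-free list of canonical categories (reflex syncope, orthostatic
hypotension, cardiac, psychogenic pseudosyncope, other), and let *y* be
the adjudicated final diagnosis.  The package computes:

- **Diagnostic yield** — the proportion of assessments proposing at least
  one diagnosis (an abstention is an explicit empty list).
- **Inclusion rate** — the proportion of assessments whose list contains
  *y*, with Wald intervals `p̂ ± z·√(p̂(1−p̂)/n)`.
- **Diagnostic Precision Score (DPS)** — per assessment

  `score = hit − q·(number of incorrect listed diagnoses)`,

  with `hit = 1{y ∈ list}` and the penalty calibrated cohort-wide as
  `q = 1/(L_max − 1)`, the reciprocal of the largest possible number of
  incorrect diagnoses in a single list (`q = 0.25` when the longest list
  holds five diagnoses).  Group DPS is the mean score per assessed
  letter, in percent; unexplained finals stay in the denominator with the
  hit impossible.
- **Diagnostic safety** for cardiac syncope, in both directions: forward
  (were Phase-1 cardiac calls vindicated by the final diagnosis?) and
  backward (how did each rater respond to the final-cardiac cases?).
- **Risk aggregation** following the ESC syncope guideline: high risk is
  any high-major feature, or a high-minor feature with structural heart
  disease, across event, history, examination, and ECG domains.
- **Inference**: Levene's test, one-way ANOVA on per-case DPS,
  Games–Howell post hoc contrasts (Welch standard errors,
  Welch–Satterthwaite degrees of freedom, studentized-range
  multiplicity control), and univariable logistic-regression odds
  ratios.

Committee adjudication is implemented too: unanimity, majority with one
abstention, consensus meeting, else unexplained.  A synthetic cohort
generator reproduces the study structure (55 cases, 12 physicians, 6
allied professionals, one AI-like rater) so the full pipeline runs and
is testable without patient data.

## Worked example

```python
import ddxeval as dx

model = dx.DiagnosticAccuracyEvaluation.from_simulation(
    dx.reference_cohort_config(seed=1)
)
results = model.fit()
print(results.summary())
```

prints

```
Differential-diagnosis evaluation
================================================================
cohort: 19 raters x 55 cases, 1045 assessments -> PASS
  cases without final diagnosis (lost to follow-up): ['C031', 'C047']
penalty per incorrect diagnosis: 0.25 (calibrated, max list length 5)

group                        yield   inclusion      DPS
-------------------------------------------------------
PHYSICIAN                    83.2%       33.0%     8.5%
ALLIED                       86.7%       19.8%    -6.3%
AI                          100.0%       50.9%   -32.5%
...
Levene W = 110.484 (p = 0.0000); ANOVA F = 12.590 (p = 0.0000) [case-mean DPS]
  PHYSICIAN vs ALLIED: diff +0.147 [0.027, 0.267], p = 0.0119
  PHYSICIAN vs AI: diff +0.410 [0.178, 0.641], p = 0.0002
  ALLIED vs AI: diff +0.263 [0.039, 0.486], p = 0.0172
```

Every rater assessed all 55 cases (1,045 assessments); two simulated
cases were lost to follow-up, so inclusion and DPS are computed on the
remaining 53.  The AI-like rater never abstains (yield 100%) and has the
highest inclusion rate, yet its long, speculative lists drive its DPS
negative — the penalty is doing its job.  The Games–Howell contrasts
(on per-case mean DPS, in score units) show physicians outperforming
both other groups.

The same pipeline runs from the shell:

```sh
ddxeval simulate --out cohort/ --seed 1
ddxeval score --assessments cohort/assessments.csv --cases cohort/cases.csv --out scored/
ddxeval report --metrics scored/metrics.csv
```

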