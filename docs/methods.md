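# Methods

## Setting and data model

The package evaluates differential-diagnosis lists produced at referral
time (Phase 1) against a reference diagnosis established by an
independent committee after structured follow-up (Phase 3).  The unit of
analysis is the *assessment*: one rater's ordered, duplicate-free list
of canonical diagnosis categories for one case.  Six categories close
the space — reflex syncope, orthostatic hypotension, cardiac syncope,
psychogenic pseudosyncope, other — plus two sentinels: `NONE` marks an
abstention (encoded as an *empty* differential, never as a list
containing `NONE`, and stored as an explicit rank-0 row so "no diagnosis
established" is distinguishable from missing data) and `UNEXPLAINED` is
reserved for final diagnoses where the committee reached no consensus.

Free-text diagnosis strings are canonicalized through an explicit,
editable synonym map.  Which clinical entities collapse into which
category (e.g. which arrhythmias count as cardiac) is a study-level
choice; the map therefore ships as configuration, and unmapped strings
are a hard error rather than a guess.

## Committee adjudication

Each committee member (default size 3) independently proposes a
diagnosis or abstains.  Automatic resolution covers exactly two
patterns: all members agree (unanimous), or all but one agree and that
one abstained (majority with abstention).  Everything else — including
two identical opinions against one *different* diagnosis, and two
abstentions with a single diagnosis — requires a consensus meeting; a
case without a meeting outcome is unexplained.  The second of those
meeting-required patterns is a genuine ambiguity in the underlying
committee rule ("two agree, one made no diagnosis" could be read to
cover two abstentions); we resolve it conservatively as
meeting-required and flag it here.  The result is invariant under
permutation of the reviewers, and a committee in which everyone
abstains is unexplained directly — no meeting is reachable from zero
diagnoses.

## Scoring

Let `q` be the penalty per incorrect listed diagnosis.  Per assessment,

    score = hit − q · n_incorrect,        hit = 1{final ∈ list},

with an empty differential scoring exactly 0.  Calibration sets
`q = 1/(L_max − 1)` where `L_max` is the longest differential observed
cohort-wide, all raters pooled: a list of length `L_max` that contains
the final diagnosis carries `L_max − 1` incorrect entries, the largest
possible number of incorrect diagnoses in a single list.  With the
observed maximum of five, `q = 0.25`.  When every list is a singleton
the penalty is undefined and calibration raises; callers may supply a
fixed scheme instead.

Eligibility differs by metric on purpose.  Yield is a Phase-1 quantity
and uses *all* assessed cases, including any later lost to follow-up.
Inclusion rate and DPS require a reference diagnosis and are restricted
to followed-up cases.  Cases adjudicated unexplained remain in the
denominator: the hit is impossible, so every listed diagnosis is
incorrect and a non-empty list scores `−q·(list length)`.  This has a
corner worth stating: with a calibrated `q = 0.25` scheme, scores on
concrete finals live in `[−1, 1]`, but a five-item list on an
unexplained case scores `−1.25`, because all five concrete categories
are then wrong.  The property tests assert both bounds separately.

One published quirk is documented rather than reconciled: the reported
AI DPS of −6.9% is printed alongside totals of −4.00/54, although
−4.00/54 = −7.4%; this package always reports the computed ratio.  Similarly, some printed percentages are truncated rather than
rounded (541/660 printed as 81.9; 148.75/648 printed as 22.9); tests
compare numeric values, not printed strings.

## Diagnostic safety

Safety means recognizing cardiac syncope.  Forward direction: Phase-1
cardiac calls are tabulated by the final-diagnosis class they received.
What counts as a "cardiac call" is mode-dependent: for AI-style raters
the rank-1 diagnosis (they always produce a ranked list); for human
groups only single, explicitly cardiac diagnoses, excluding multi-item
lists.  Backward direction: for every (rater, final-cardiac case) pair
the response is classified as a single cardiac diagnosis, cardiac within
a multi-item list, no diagnosis, or — when cardiac appears nowhere — the
rank-1 category given.  Classifying cardiac-free multi-item lists by
their first-proposed diagnosis is a package choice; the enumerated
response classes in the source only name single categories, but its AI
results are described by first-listed diagnosis, and this rule matches
that reading.  The backward miss rate is the share of pairs in which
cardiac appeared nowhere.

## Risk aggregation

Four documentation domains (syncopal event, history, examination, ECG)
each carry one of: not mentioned, low risk, high-risk minor, high-risk
major.  A case is high risk with any high-major feature, or a
high-minor feature plus structural heart disease; high-minor without
structural heart disease is reported separately; all-low is low risk;
nothing documented is unclassifiable.

## Inference

- **Wald intervals** for proportions, on the percentage scale, not
  clipped: the published interval bounds reproduce to one decimal under
  the Wald form (they do not under Wilson or exact intervals), which
  fixes the choice.
- **Levene's test** (mean-centered by default, matching the named test;
  median-centering available) and **one-way ANOVA** delegate to
  scipy.stats behind the module surface, with zero-variance degenerate
  input mapped to a zero statistic instead of NaN.
- **Games–Howell** is implemented in the package (no scipy/statsmodels
  implementation exists): per pair, Welch SE `√(v_a/n_a + v_b/n_b)`,
  Welch–Satterthwaite df, p from the studentized-range distribution with
  k groups evaluated at `|diff|/se·√2`, and CI half-width
  `q_crit/√2·se`.  Zero-variance groups are flagged; identical-constant
  pairs return p = 1 with a point interval.  The unit tests cross-check
  every number against pingouin's independent implementation.
- **Logistic odds ratios** come from a maximum-likelihood univariable
  fit (statsmodels `Logit`) with Wald intervals; separation raises an
  explicit error rather than returning a huge estimate.

The group comparison of precision scores supports two aggregations, and
the ambiguity is real: the source design mixes a per-case mean over 18
professionals with a single AI value per case, without stating whether
the variance of that mean was adjusted.  `agg="case-mean"` (default)
compares one value per followed-up case per group — the mean across the
group's raters — with the AI contributing its raw per-case score;
`agg="rater"` pools per-assessment scores instead.  Both are exposed;
neither is privileged by the published description.

## Synthetic cohort generator

The generator emulates the study structure, not patient-level clinical
reality.  Per case a true diagnosis category is drawn from the
adjudicated distribution (reflex 25/54, unexplained 13/54, orthostatic
hypotension 11/54, cardiac 4/54, psychogenic pseudosyncope 1/54); one
case in 55 is expected to be lost to follow-up, which removes the
recorded final but keeps the Phase-1 assessments.  Per rater and case:
abstain with probability `abstain_prob`; otherwise draw a list length
from a discretized truncated normal (round, clamp to `[1, max]`) —
chosen because only mean ± SD and the maximum are reported — include the
true diagnosis with probability `include_prob` at a uniformly random
rank, and fill remaining slots without replacement from the rater's
`error_bias` distribution over wrong labels.  A miss list is capped at
the number of available wrong categories (four when the final is
concrete, five when unexplained).

Default archetypes: physician-like (abstain 0.18, length 1.49 ± 0.72),
allied-like (abstain 0.155, length 1.31 ± 0.58), AI-like (never
abstains, length 4.02 ± 0.77, reflex-heavy error bias with frequent
speculative cardiac mentions).  Abstention rates and list-length moments
are observed group statistics; the include probabilities (0.55 / 0.42 /
0.80) are calibration choices, not measurements.  Note that with these
parameters the simulated inclusion rates and DPS sit below the published
observed values (e.g. AI DPS near −23% rather than −7%), because
inclusion there conditions implicitly on behaviour the generative model
does not encode (the published AI hit every concrete-final case); the
generator is a test harness for the *pipeline*, and passing tests show
internal consistency of estimator and model, not fidelity to any
particular clinic's raters.  Abstention is independent of case
difficulty — no joint structure is documented to emulate — and
questions/tests/interventions counts are Poisson pass-through fields.

Randomness: one global seed; the case stream and each rater's stream are
independent substreams derived via `SeedSequence` with a stable CRC32
hash of the rater id, so adding a rater never perturbs existing draws
and equal seeds give byte-identical output tables.

### Analytic expectations and parameter recovery

The expected per-assessment score is computed by exact enumeration of
the generative rules (abstention × final category × hit × list length,
with the same miss-list cap as the sampler), and the include probability
is recovered as the hit frequency among non-abstained assessments of
concrete-final cases — unbiased under the model.  The recovery
experiment regenerates the reference cohort (55 cases × 19 raters)
across 200 replicates and tabulates z-scores of mean estimate against
truth with Monte-Carlo standard errors; all must fall within ±3.  Two
hundred replicates keep the experiment near ten seconds on one CPU
while leaving the Monte-Carlo error well below the effects of interest.

## Numerical and formatting choices

Percentages are printed to one decimal in human-readable reports;
CSV/JSON outputs keep full precision.  Scoring is exact rational
arithmetic in floating point (penalties are dyadic at the default 0.25,
so sums like 148.75 are exact).  Output files are deterministic byte-
for-byte for identical inputs and seed.

## Known limitations

- The generator models category-level behaviour only: no free-text
  letters, no rank-position structure beyond the uniform hit rank, no
  correlation between raters on difficult cases.
- The closed category set pushes all clinical granularity into the
  synonym map; a cohort needing finer outcome classes (e.g. separating
  arrhythmic from structural cardiac syncope) needs a different label
  space.
- Wald intervals degenerate at 0% and 100% and can cross the [0, 100]
  bounds near the edges; they are used because they are the published
  interval form, not because they are optimal.
- Games–Howell p values rely on the studentized-range distribution's
  numerical integration in scipy; agreement with pingouin is to 1e-6,
  not machine precision.
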