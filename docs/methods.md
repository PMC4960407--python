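# Methods

## The scoring model

The unit of analysis is a suicide-risk **assessment**, not a patient: a
patient assessed several times contributes several rows, each with its own
look-back history and its own 90-day outcome. Assessments are labelled
*risk* if the patient attempted suicide within the 90 days after the
assessment and *control* otherwise; the label is an input column, never
derived by this package.

Features are counts of ICD-10-coded diagnoses per **chapter heading** per
**look-back window**. The 18 headings are the 22 WHO (2015) chapters with
chapter V (mental and behavioural disorders) removed — the method's premise
is to use *physical* illness only — chapters XVI (perinatal) and XVII
(congenital) removed as absent in an adult psychiatric cohort, and chapters
VII + VIII merged into one sensory-organ heading. Chapter membership is
resolved at the letter+two-digit level (the D48/D50 and H59/H60 boundaries
split on the numeric part); finer ICD-10-AM detail is irrelevant at chapter
granularity. Codes falling in a gap between chapters are excluded with a
warning rather than rejected, since hospital exports contain local codes.

The five windows are 91, 182, 365, 730 and 1460 days (3, 6, 12, 24, 48
months at 30.4 days/month). Fixed day counts, rather than calendar-month
arithmetic, make window membership deterministic across locales and
month-end edge cases. Windows are half-open, `[date − len, date)`: a
diagnosis coded on the assessment day itself is never counted, so
same-day coding of the index event cannot leak outcome information into the
features. Windows are nested, so counts are non-decreasing in τ — an
invariant the test suite enforces.

The **lookup table** pt(τ, ch, j) is the only fitted object. Nonzero counts
are binned into j ∈ {1–2, 3–5, 6–10, 11–20, >20}; zero counts belong to no
bin and contribute nothing anywhere (absence of history is treated as
uninformative, not protective). The default cell estimate is the
*normalized ratio*: each group's histogram row over bins is first scaled to
within-group proportions h, and pt = h_R / (h_R + h_C). With ~12% of
assessments in the risk group, a raw-count ratio (available as the
`raw-ratio` variant) would concentrate nearly all cells far below ½ and a
½ threshold would almost never fire; the normalized form asks the
discriminative question — *is this bin relatively more typical of risk than
of control histories?* — independently of class imbalance. Cells empty in
both groups are undefined (NaN, serialized as `null`), logged, and score 0.

Scoring thresholds each looked-up pt with a Heaviside step at θ (default
0.5, the natural pair to the normalized ratio; configurable). Ties at the
threshold fire — the boundary is assigned to risk — a documented and tested
convention. The default score is the plain sum of indicators over the
model's (τ, ch) cells; the `weighted` mode sums pt·indicator instead, for
users who want graded contributions. All estimator and scorer outputs are
bit-deterministic given their inputs, and both are verified exactly against
independent nested-loop recomputations on small cohorts.

## Evaluation

AUC is the tie-corrected Mann–Whitney statistic (computed via average
ranks); integer-valued scores tie constantly, so half-credit handling is
essential, and the implementation is property-tested against the pairwise
brute-force definition and against scikit-learn.

The cross-validation splits assessments into k = 10 seeded folds of
near-equal size; each fold is scored by a lookup table built on the other
nine, so no assessment contributes to its own score. The headline statistic
is the mean AUC over folds; per-fold values are always retained in the
report. By default the evaluated set is the assessments with clinical
rating > 0 (~92% of the cohort — the basis on which the rating is defined);
`evaluated_set: all` lifts the restriction. The clinical baseline itself
involves no fitting and is reported as a single whole-set AUC; whether that
set is "all" or "rated" changes the value by ~0.01, and both are available.
The combined score is ordinary least squares of the binary outcome on
intercept + algorithm score + clinical rating, refit inside every training
fold and applied to the held-out rows; a constant covariate (possible in
degenerate folds) is dropped with a warning rather than producing a
rank-deficient solve. Folds whose training or test part contains a single
class are skipped, logged and listed in the report.

Because the evaluation unit is the assessment, two assessments of one
patient can land in different folds; this mirrors the method's stated
protocol, but it is a real leakage hazard, so `make_folds(unit="patient")`
keeps each patient's assessments in one fold for sensitivity analyses.

## The synthetic cohort generator

The generator's job is to reproduce the statistical structure the method
assumes, so that pipeline behaviour on it is informative: a cohort of
16,858 assessments from ~7,400 patients, 12.29% risk prevalence, group
frequency-distribution marginals matching the packaged reference tables,
and a clinical rating with tunable, weakly discriminative AUC
(default target 0.56).

Diagnosis codes arrive in **episodes**: an admission generates a batch of
codes sharing one date. Per patient, a gamma frailty g (mean 1, shape k)
scales a Poisson episode process; episode dates before the patient's most
recent ("index") assessment follow a piecewise-constant recency profile
over the five window segments; each episode emits 1 + NB(a, c − 1) codes
spread over headings by fixed group weights. Three structural features are
load-bearing:

- **Shared frailty** correlates counts across headings and windows. Under
  heading-independence, matching the per-heading prevalences forces the
  probability of *no* history at 48 months to ~2.5% for controls, versus
  the observed 16.9%; comorbidity clustering is not optional.
- **Episode batching** decouples whether a window holds any history (the
  episode process) from how many codes it holds (batch sizes). A plain
  per-heading negative-binomial count model cannot simultaneously match the
  control group's no-history fractions and its nearly flat 48-month bin
  profile; the compound (stopped-sum) form can.
- **The recency profile** lets expected counts concentrate near the
  assessment, as the reference tables require (risk histories are
  front-loaded).

Calibration runs at package run time from the packaged fixture CSVs, never
from frozen constants. Per group: episode means e_τ are solved in closed
form so every per-window no-history fraction matches **exactly in
expectation** ((k/(k+e_τ))^k = z_τ); (k, a, c) are fitted by least squares
to the five windows' total-count bin masses, computed analytically with the
Panjer recursion for the compound negative binomial; heading weights are
Poisson-implied intensities −log(1 − prevalence) from the 48-month
per-heading prevalences. Achieved model-expectation error is ≤ 4.2
percentage points per cell, and a full-size simulated cohort stays within
5 points of every reference cell; `calibration_report()` *measures* this on
any generated cohort rather than assuming it.

Clinical ratings discretize a latent normal at cutpoints fixed by the
control marginal (8% rated 0, matching ~92% positively rated); the risk
group's latent shift is solved by root-finding so the exact tie-corrected
AUC between the group distributions equals the target. Targets ≥ 0.95 are
infeasible for a five-level rating with this control marginal and are
rejected. Repeat assessments of one patient fall within a week before the
index assessment (re-assessment during a single admission), so all of a
patient's rows see essentially the same history; outcome labels equal the
patient's group.

What the generator does **not** emulate — and hence what passing tests do
not establish about real EMR data: realistic within-heading code choice
(codes are uniform within letter ranges), demographic structure (no
age/sex), longitudinally spread re-assessments, heading-level correlation
beyond the shared frailty, outcome labels derived from post-assessment
coding, and any drift of practice over calendar time. Directional results
(history-based scores beating a 0.56-AUC clinical rating; longer look-back
helping; pooled windows matching or beating single windows) are
demonstrated on this synthetic structure only.

## Numerical and interface conventions

- Table percentages round half-up to 2 decimals (`Decimal`-based), matching
  how printed clinical tables round; the packaged fixture percentages all
  recompute exactly from their counts under this rule.
- Lookup JSON serialization is lossless (NaN ↔ `null`) and round-trip
  tested; CSVs are UTF-8, comma-separated, ISO-8601 dates, with eager
  schema validation that names the file, row and column of a violation.
- All randomness flows through `numpy.random.default_rng(seed)`; seeds are
  mandatory in generator configs, and identical seeds give byte-identical
  CSV outputs.
- Default problem sizes: the full-scale evaluation and the acceptance
  script use the cohort's natural size (16,858 assessments; ~15,500
  evaluated after the rated-subset rule; ~190,000 diagnosis rows), which
  runs in seconds; the null-cohort check uses 5,000 assessments, ample to
  put chance AUCs inside [0.45, 0.55].

## Known limitations

- The lookup table applies no smoothing or shrinkage; sparse cells are
  noisy or undefined, and scores are not calibrated to absolute risk.
  (Deliberate: the method's appeal is its transparency.)
- The binary Heaviside sum discards the margin by which a cell exceeds θ;
  the weighted mode recovers some of it but is still not a probability.
- Counting code occurrences (not distinct episodes) means administratively
  duplicated codes inflate features; with episode-batched synthetic data
  this is visible as heavier-than-nominal bins and is one reason the
  fixture match is approximate rather than exact.
- Assessment-unit cross-validation shares patients across folds; use the
  patient-unit option to bound the effect.
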