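# Methods

`psbridge` implements a patient-level indirect comparison of two
antipsychotic treatment programs — paliperidone extended-release (ER)
6–12 mg/day and oral immediate-release risperidone (2–4 and 4–6 mg/day) —
pooled from six short-term, double-blind, placebo-controlled schizophrenia
trials (three per compound).  Because the two programs were never compared
head to head, comparison groups are constructed by propensity-score
matching and contrasted on last-observation-carried-forward (LOCF)
endpoints and placebo-adjusted adverse-event (AE) rates.  This note
records the statistical model, the calibration of the synthetic cohort
generator, numerical conventions, and the design decisions taken where the
published methodology leaves latitude.

## 1. Analysis population

Six trials are modelled with their design constants: three 6-week
paliperidone ER trials (PALI-SCH-303/304/305, PANSS entry window 70–120),
and three risperidone trials — RIS-USA-1 (6-week flexible dose, BPRS-based
entry, no factor scores), RIS-INT-3 (8-week, PANSS 60–120) and RIS-USA-72
(4-week, PANSS 80–120, no CGI-S).  Inclusion screens: age 18–65 inclusive,
risperidone modal dose ≤ 8 mg/day, exclusion of subjects whose prior
antipsychotic exposure was exclusively atypical (a surrogate for the
conventional-prior requirement applied to the paliperidone trials).  Dose
groups are assigned from the modal daily dose; a risperidone subject at
exactly 4 mg/day belongs to **both** risperidone dose groups.  This dual
membership is represented as two group *views* over one underlying subject
set; a subject never contributes two rows to a single statistical model.

## 2. Propensity model and matching

The propensity score is the fitted probability from a maximum-likelihood
logistic regression of group membership on age, sex, race (white vs all
other), baseline BMI, baseline CGI-S and baseline PANSS total.  Subjects
with a missing covariate are dropped and logged (no imputation — the
source methodology does not mention any, and this choice is flagged as
unconfirmed).  Zero-variance covariates are absorbed by the intercept.
(Quasi-)separation is detected from the magnitude of the linear predictor
(> 30) and raised as an error advising covariate review.

Matching is greedy, hierarchical and 1-to-many with a caliper of 0.05 on
the **probability** scale (the scores are probabilities, and the published
description attaches the 0.05 caliper directly to them).  In each pass,
cases are visited in ascending id order and each claims its nearest
still-unclaimed control within the caliper; passes repeat — one additional
control per case per pass — until a pass adds no pair.  Ties between
equidistant controls go to the lower control id; both conventions exist
only to make the algorithm deterministic.  Each control is used at most
once; a `max_ratio` option caps controls per case (default unlimited — the
published scheme states no cap).

The matched population is built in three steps: (1) risperidone (all
doses) vs the risperidone-program placebo; (2) paliperidone ER vs the
paliperidone-program placebo; (3) a propensity model **refit** on the
step-1/2 active survivors with compound program as the outcome, matched
across compounds.  In each step the smaller group serves as cases, which
maximizes retention under 1-to-many growth.  All subjects matched in step
3 enter the final sample together with the placebo groups retained in
steps 1–2.  Models are fit per program, not per trial.

Balance is reported as per-group means (SD) / counts (%) plus absolute
standardized mean differences, |m₁ − m₂| / √((s₁² + s₂²)/2) (binary
covariates use p(1−p) variances).

### Placebo poolability

Before efficacy analysis the two program placebo groups are compared on
baseline covariates (two-sample t and chi-square tests) and on endpoint
LOCF changes for PANSS total and the five factor scores
(baseline-adjusted ANCOVA contrasts).  The groups are pooled for efficacy
if and only if every endpoint-change p-value exceeds 0.05.  AE
comparisons never use the pooled placebo group: each compound is corrected
by its own program's placebo.

## 3. Efficacy endpoints

The LOCF endpoint is the last observed post-baseline value at or before
the trial's endpoint week (4 for RIS-USA-72, 8 for RIS-INT-3, 6
otherwise); completers contribute the endpoint-week visit itself.
Subjects with no post-baseline value are excluded from change analyses and
logged.

Group contrasts come from ANCOVA: change ~ treatment + baseline, with
homogeneous slopes (no treatment×baseline interaction — standard practice;
the source states only that baseline was the covariate).  Adjusted means
are least-squares means at the grand baseline mean; pairwise differences
carry model-based standard errors and two-sided t-distribution p-values;
no multiplicity adjustment is applied.  A zero-variance baseline is
dropped with a warning (the contrast degrades gracefully to a one-way
ANOVA on changes) rather than failing, so degenerate inputs remain
analyzable.  Because the two risperidone dose groups overlap in the 4
mg/day subjects, contrasts are computed from separate two-group models per
comparison, never from a single model containing both dose groups.

A responder shows a ≥ 30% decrease in PANSS total from baseline at the
LOCF endpoint; the inequality is evaluated exactly on the integer scores,
so exactly 30% counts as response.  Responder percentages use the LOCF
analysis set as denominator (the published denominators are unstated).
Rates are compared with Pearson's chi-square without continuity
correction.

## 4. Safety

AE incidence counts each subject once per preferred term; percentages are
rounded to one decimal, halves away from zero (the convention consistent
with every checkable published cell).  The placebo-adjusted differential
between compounds is

d = clamp(risperidone % − placebo(RIS) %) − clamp(paliperidone ER % − placebo(PALI) %)

with clamp(x) = max(x, 0).  The differential is computed on the
**already-rounded** percentages: only round-then-difference reproduces the
published cells (e.g. somnolence vs risperidone 2–4 mg/day gives 7.3 on
rounded inputs but 7.2 on raw fractions).  A term enters the comparison
table when any active or placebo group incidence reaches 5%; a
differential is reported when its magnitude reaches 2.0 points, else NA,
with direction from the sign before the magnitude.  Two internal quirks of
the published table are worth noting: one term (akathisia, maximum
incidence 4.7%) sits below the table's own 5% entry gate yet is printed,
so the packaged reproduction recomputes differentials on the published
term list without re-applying the gate; and one count/percentage pair
(somnolence, risperidone 2–4 mg/day, 10 subjects printed as 8.9%) is one
rounding step away from its stated denominator.  Weight change is
analyzed with the same ANCOVA machinery as the efficacy endpoints.  No
statistical tests are applied to AE rates.

Placebo-adjusted completion rates are differences of one-decimal
percentages (rounded active minus rounded program placebo).  The p-values
attached to such contrasts in the source have no stated method; the
package emits the adjusted rates without p-values.

## 5. Synthetic cohort generator

The generator emulates the *matched* analysis population, since that is
the population whose summaries are published: arm sizes 179 / 113 / 129
(63 subjects at 4 mg/day shared between the risperidone groups) / 95 /
122, spread over the six trials.

**Covariates.**  Continuous baselines are truncated normals (age on
[18, 65], BMI on [16, 45], PANSS on the trial's entry window, CGI-S on
[1, 7] as a rounded integer).  The location parameter is calibrated
numerically (Brent root-finding) so the mean of the truncated — and, for
integer scales, rounded — distribution equals the published target; an
uncalibrated location would miss the target by the truncation shift.
Binary covariates (sex, race) are Bernoulli at the published proportions.
Targets come from the published matched-group baseline tables, with one
correction: the per-group placebo race percentages (91.6%/93.6% white) are
inconsistent with their own printed counts and with the pooled-placebo
value (138/217 = 63.6%), so both placebo groups use the
denominator-consistent 63.6%.  SDs are matched before truncation, so
realized SDs run slightly below their targets; only means are calibration
targets.

**Outcomes.**  Each subject draws a latent total PANSS change at the
endpoint scale; the within-subject trajectory is linear, f(t) = t/W, with
independent N(0, 3²) visit noise, integer rounding and clamping to
[30, 210].  Factor scores partition the total through fixed non-negative
shares derived from the published factor-level changes (each group's
factor changes normalized by its total change; the placebo
hostility/excitement share, which would be negative because that factor
worsens while the total improves, is clamped to zero and the shares
renormalized).  Baseline factor scores split the baseline total by the
factor item counts (7/8/4/7/4 of 30 items).  CGI-S and weight changes
follow the same linear-gain construction with their own noise scales;
RIS-USA-72 visits omit CGI-S, matching its design.

**Dropout and LOCF calibration.**  Dropout is outcome-independent
(missing completely at random) by default: a constant weekly hazard h
solved from (1−h)^W = completion rate, with post-dropout visits removed.
Because LOCF endpoints under a linear trajectory are attenuated by the
factor E[L/W | L ≥ 1] (L = last retained week), the latent effect is
divided by this analytically computed factor, so the realized mean LOCF
change per arm equals the arm's `endpoint_effect`.  An optional hazard
dependence on the subject's own improvement
(`dropout_improvement_slope`) is provided to stress-test LOCF's known
fragility; it is off by default.

**Overlap-consistent dose strata.**  The published effect, completion,
CGI and weight targets are *group* means of overlapping groups.  The
generator therefore works at three dose strata (2–3, exactly 4, 5–6
mg/day; sizes 50/63/66), sets the shared 4 mg stratum to the midpoint of
the two group targets and solves the outer strata from the two group-mean
identities.  The solution produces a monotone dose-response (PANSS change
≈ −7.1 / −15.2 / −22.1) and reproduces both published group means exactly
in expectation.

**Adverse events** are independent Bernoulli draws per preferred term at
the published incidences (stratum-solved for risperidone, clamped to
[0, 1]); no within-subject correlation is modelled, since only marginal
incidences are published.  Onset weeks are uniform over the subject's
observed weeks.

**What the generator does not emulate**, and hence what passing tests do
not demonstrate about real data: effect targets are published
*covariate-adjusted* LS means treated here as raw arm means (baseline and
change are generated independently, which makes the two coincide in
expectation); responder percentages are emergent rather than calibrated —
a normal change distribution with the published mean and SE-implied SD
cannot reach the published 55.1% response, so the published response
rates and change means are not jointly reproducible under normality;
there is no item-level PANSS structure, no dose-exposure relationship, no
EPS rating scales, no prolactin, and AE terms arrive pre-coded (no
MedDRA hierarchy).

## 6. Numerical conventions and problem sizes

* Percentages: one decimal, halves away from zero (`decimal` arithmetic,
  not binary-float `round`).
* Propensity fits: Newton-Raphson, tolerance-stable to refitting (< 1e-8
  coefficient reproducibility); scores clipped away from {0, 1} by 1e-12.
* ANCOVA: explicit normal-equations design with a centered baseline
  column, so adjusted means read directly off the coefficients.
* Determinism: one `numpy` Generator seeds the whole cohort draw; fixed
  (suite, seed) gives byte-identical output tables, and the pipeline
  writes no timestamps.
* Test problem sizes were chosen to make Monte-Carlo bands tight while
  keeping the default suite fast: 110 replicates for contrast recovery,
  500 for the type-I-error band, 10 pooled replicates for completion
  calibration, 20 seeded runs for balance-shrinkage, 250 random instances
  (≤ 6×8) for the matching oracle.

## 7. Known limitations

* The matched population emulated by the generator is already balanced,
  so default-suite matching exercises retention rather than bias
  removal; the confounded variant (`with_covariate_shift`) exists for the
  latter.
* LOCF is implemented faithfully but is a known-fragile estimand under
  informative dropout; the optional outcome-dependent hazard lets users
  quantify that fragility, not correct it.
* The published "Active − placebo" response differences (26.9/28.5/23.4)
  are not plain subtractions of the printed rates; their derivation is
  unstated and they are not reproduced.
* Completion-rate contrasts carry no p-values (method unstated in the
  source).
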