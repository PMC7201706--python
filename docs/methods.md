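# Methods

## Study design

The package implements a nested case-control analysis of coded primary-care
records.  The cohort is every patient in a record set; cases are incident
coded diagnoses of ankylosing spondylitis (AS); controls are sampled by
incidence density: for each case, patients of the same sex and GP practice,
within ±2 years of age, registered and AS-free at the case's **index date**
(the case's diagnosis date, which all members of the matched set share).
Two comparisons are run throughout: *population* controls (any eligible
patient) and *symptomatic* controls (patients with a coded spinal symptom
or non-AS spinal diagnosis on or before the index date).  The second
comparison asks the clinically sharper question: among patients presenting
with back trouble, what distinguishes the future AS case?

### Incident-case rules

- first coded AS diagnosis inside the study window (default
  2000-01-01 to 2010-12-31), age at diagnosis 18–50 completed years,
  bounds inclusive (a patient aged exactly 50 is retained; 51.0 excluded);
- diagnosis at least 365 days after registration start (earlier diagnoses
  are likely prevalent disease re-coded at registration, and leave no
  pre-diagnosis record to analyse);
- no DMARD prescription more than 30 days before the coded diagnosis
  (prevalent disease coded late).  "1 month" = 30 days and "1 year" = 365
  days throughout: the source conventions never define month/year
  arithmetic for these leads, so fixed-day conventions are used and
  documented here.

When more than 4 eligible controls exist, 4 are drawn uniformly without
replacement from a seeded generator whose stream is a deterministic
function of (seed, comparison, case ordinal), so cohort construction is
reproducible and independent of iteration order.  A patient may serve as a
control for several cases (logged); a case with an empty pool is dropped
from that comparison only.

## Features

Every feature is binary — present/absent within a horizon — because coded
records support presence far more reliably than counts; multiple distinct
episodes are captured instead by the *separate* relation.  Relations:

| relation  | definition | threshold |
|-----------|------------|-----------|
| single    | ≥ 1 event of X in horizon | — |
| proximity | some X and some Y in horizon with \|Δdays\| ≤ N, either order | inclusive |
| separate  | two *consecutive* X in horizon with gap > N days | strict |
| exclusive | ≥ 1 X in horizon and no Y **anywhere** in the record | — |

"Within N days" is inclusive and "separated by more than N days" strict,
matching the relations' names literally.  The *exclusive* veto scans the
whole record, not the horizon: "without ever" means ever.  The default
roster holds 9 single features (axial pain, other spinal diagnoses,
sciatica, large- and other-joint symptoms, tendon disorders, iritis,
fatigue, NSAIDs) and 10 composites (axial pain within 30 days of an NSAID,
within 360 days of a large-joint symptom, separated by 180/360 days,
without ever sciatica, tendon disorders separated by 180 days or within
360 days of axial pain, FBC within 90 / ESR within 180 / iritis within 360
days of axial pain).

Horizons are the whole pre-index record ("any_time") and 3-year windows
ending 0, 3, 6, 12, 18, 24 and 36 **calendar months** before the index
date.  Month offsets clamp at month end (Mar 31 − 1 month → Feb 28/29);
windows are half-open `[start, end)`, so a boundary day never counts twice
and an index-day event is in no window.  For windowed analyses each member
must have been registered ≥ 365 days before the window's end (the date the
gap begins).  The anchor is genuinely ambiguous between window end and
window start; the end is the default and a switch
(`eligibility_anchor="start"`) exposes the alternative.  Ineligible
controls are dropped individually, and the whole set is dropped when its
case is ineligible, preserving the matched structure.

Same-day duplicate codes are retained on input; presence/absence coding
absorbs them.  Events dated outside the registration spell raise a warning
but are kept (registration dates in real extracts are themselves noisy).

## Estimator

For one binary exposure and matched sets of one case with m controls, the
conditional likelihood per set is `exp(β x_case) / Σ_j exp(β x_j)`.  With
exchangeable binary exposures each set reduces to (size, total exposed t,
case exposed), giving denominator `t e^β + (size − t)`.  Concordant sets
(t = 0 or t = size) contribute exact constants; the Newton–Raphson
iteration (start β = 0, step-halving, |score| < 1e-8 or |Δβ| < 1e-10,
max 100 iterations) therefore runs on the informative sets only, so adding
concordant sets cannot perturb the estimate even in the last bit.  The fit
internally canonicalises the exposure orientation (fitting the
lexicographically smaller encoding and negating back), which makes
"complement every exposure ⇒ −β" an exact identity rather than a numerical
approximation.

SEs are observed-information (`1/√I(β̂)`); CIs are Wald on the log scale —
consistent with the symmetric-on-log-scale intervals conventionally
reported for this design.  **Separation** (every informative set has the
case exposed, or none does) makes the MLE infinite; such fits are flagged
non-estimable and rendered as "-" in tables.  No penalised (Firth)
fallback is fitted by default — a non-estimate is more honest than a
prior-dependent number in tables this sparse.  Rendered tables additionally
suppress estimates with fewer than 5 exposed subjects in total
(`min_exposed_for_report`, configurable); this mimics the common
sparse-cell convention and is recorded per row in the `suppressed` column,
distinct from `estimable`.

Only single-covariate models are fitted: each feature is tested separately,
matching the design's screening purpose.  No multivariable adjustment,
stratified-Cox reformulation or exact conditional inference is in scope.

## Synthetic records

The generator is the package's test bed, not a clinical simulator.  Each
patient gets one registration spell (opening 1–6 years before the study
window) and per-category homogeneous Poisson event streams.  Case status
multiplies category rates by fixed rate ratios, and one category (axial
pain) additionally carries a linear intensity **ramp** for cases, from
multiplier 1 at 36 months before diagnosis to 4 on the diagnosis day —
the mechanism that produces a rising OR as the analysis window approaches
diagnosis.  NSAID prescriptions are additionally *coupled* to axial-pain
events (probability 0.5 of a prescription within a uniform 0–30-day lag),
so proximity composites have a real signal to detect.  An optional
under-coding probability thins events to emulate sparse symptom coding
(default off).

Defaults were fixed once from the published control-group 3-year
prevalences (rate = −ln(1−p)/3 per person-year, e.g. axial pain 0.037/yr
from 10.5%) and published effect sizes as rate-ratio analogues; the
axial-pain multiplier (3.0, with the ramp on top) and the NSAID multiplier
(3.5, with coupling on top) were chosen so the *case* 3-year prevalences
(~55% and ~70%) match the published ones, since rate ratios and odds
ratios diverge at these prevalences.  Cases are ~72% male, aged 18–50 at a
diagnosis date uniform over the study window.

Randomness uses one root seed with per-patient counter-derived substreams
(`SeedSequence(seed, spawn_key=(patient,))`), so output is identical across
platforms and iteration orders.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: calendar drift in coding practice (e.g. the
improvement in test recording in later years), inter-practice rate
heterogeneity, within-patient event clustering beyond the NSAID coupling,
registration churn (every spell is open-ended), and informative
under-coding.  Rate *ratios* are not odds ratios: the mapping was
calibrated empirically by large-sample pipeline runs (a rate ratio of 5 on
large-joint symptoms yields a conditional log-OR of 1.716, calibration SE
0.059, frozen as a regression value in the test suite) rather than claimed
as an identity.

## Reporting conventions

Percentages are 100·n/N to 1 decimal.  ORs ≥ 1 print with 1 decimal,
< 1 with 2.  Lead-time histograms use 1-year left-closed bins on floored
year counts (year 0 = less than 1 year before the index date); medians and
IQRs are computed on unfloored values (days/365.25).  Trend series carry
non-estimable points flagged, never silently dropped, and a missing
horizon is an assembly error rather than a gap in the plot.

## Problem sizes

Defaults are sized for a laptop: the default simulation is 4,000 patients
(~80 cases) across 12 practices, and the bundled acceptance script runs
6,000.  The null-pipeline and signal-recovery checks in the test suite use
4,000 patients and 20 replicates of 2,000 respectively; the Wald-coverage
check uses 500 replicates of 200 matched sets.  All scale linearly in
patients and replicates for users who want tighter Monte-Carlo error.

## Known limitations

- One registration spell per patient; multiple spells at one practice are
  out of scope.
- The symptomatic-control qualifying codes must precede the index date;
  whether "has spinal codes" should instead mean "ever" is arguable, and
  this choice is a package decision, not a fact about the design.
- Composite features evaluate their positive components within the
  horizon; only the *exclusive* veto looks outside it.
- The abstract-style phrase "within the same year" is implemented as the
  360-day proximity composite; no calendar-year variant exists.
- Wald CIs undercover slightly in very sparse strata; profile-likelihood
  intervals are a possible extension.
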