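# prodroma

Nested case-control analysis of pre-diagnosis clinical features in coded
primary-care electronic health records, built around the long prodrome of
**ankylosing spondylitis (AS)**: years of non-specific back pain, NSAID
prescriptions and related consultations typically precede the coded
diagnosis.  The package is for epidemiologists and health-data scientists
who want to quantify how strongly coded features — individually and in
clinically motivated *composite* form — are associated with a later
diagnosis, and how those associations evolve as diagnosis approaches.

Because real primary-care extracts are access-controlled, the package ships
a seeded synthetic EHR generator with known ground truth, so the entire
pipeline is runnable and testable out of the box.

## What it computes

1. **Matched cohort construction.**  Incident cases are patients with a
   first coded AS diagnosis inside a study window (default 2000–2010), aged
   18–50 at diagnosis, registered ≥ 1 year before diagnosis, and without a
   DMARD prescription more than 30 days pre-diagnosis (a marker of
   late-coded prevalent disease).  Each case is matched (sex, GP practice,
   age within ±2 years) to up to four *population* controls and up to four
   *symptomatic* controls (patients with prior spinal codes), all AS-free
   and under observation at the case's index date — incidence-density
   sampling with the index date shared across the set.

2. **Temporal feature engineering.**  Binary presence/absence of each
   feature per patient per horizon: any time before the index date, and
   3-year windows ending 0, 3, 6, 12, 18, 24 and 36 calendar months before
   it.  Composite relations:
   - *proximity*: X within N days of Y, either order (|Δ| ≤ N);
   - *separate*: two consecutive X more than N days apart (distinct
     episodes, not one multi-code episode);
   - *exclusive*: X present, Y never present anywhere in the record.

3. **Conditional logistic regression.**  For a matched set with exposures
   `x_1..x_{m+1}`, the conditional likelihood of the case being the
   diseased member is

   ```
   P(case | set) = exp(β x_case) / Σ_j exp(β x_j)
   ```

   which eliminates the per-set nuisance intercepts; `exp(β)` is the odds
   ratio.  The MLE is found by Newton–Raphson with step-halving
   (implemented from scratch; cross-checked against statsmodels in the test
   suite), with observed-information SEs and 95% Wald CIs.  Separated data
   (e.g. no exposed controls anywhere) are reported as *non-estimable*
   rather than given a spurious estimate, and sparse cells (fewer than 5
   exposed in total, configurable) are suppressed in rendered tables.

4. **Reporting.**  Case-control OR tables, first-occurrence lead-time
   summaries (median/IQR and 1-year histograms), and OR-versus-gap trend
   series as tidy CSV (optionally matplotlib plots).

## Worked example

```python
from prodroma import SimulationConfig, run_pipeline, lead_time_summary

cfg = SimulationConfig(n_patients=6000, n_practices=18, seed=1)
out = run_pipeline(cfg)          # simulate -> match -> features -> fit

r = out.results
ax = r[(r["feature"] == "axial_pain") & (r["comparison"] == "population")]
for h in ("gap_36", "gap_24", "gap_12", "gap_0"):
    row = ax[ax["horizon"] == h].iloc[0]
    print(f"{h:>7}: OR {row['or']:5.1f}  (95% CI {row['ci_low']:.1f} to {row['ci_high']:.1f})")

lt = lead_time_summary(out.records, out.cohort, "axial_pain")
print(f"median lead time {lt.median:.1f} years (IQR {lt.q1:.1f} to {lt.q3:.1f}, n={lt.n})")
```

prints

```
 gap_36: OR   6.3  (95% CI 3.7 to 10.8)
 gap_24: OR   6.9  (95% CI 4.0 to 11.9)
 gap_12: OR   7.8  (95% CI 4.6 to 13.2)
  gap_0: OR  10.2  (95% CI 6.2 to 16.7)
median lead time 4.7 years (IQR 2.4 to 8.6, n=98)
```

The axial-pain odds ratio versus population controls rises as the 3-year
window approaches diagnosis — the generator's pre-diagnosis intensity ramp
recovered by the analysis — and half of the cases had their first coded
axial-pain episode more than 4½ years before diagnosis.

The estimator can also be used directly, statsmodels-style:

```python
from prodroma import ConditionalLogit, ExposureSet

sets = (
    [ExposureSet(f"d{i}", True, (False,) * 4) for i in range(9)]     # case exposed
    + [ExposureSet(f"e{i}", False, (True, False, False, False)) for i in range(3)]
    + [ExposureSet(f"c{i}", False, (False,) * 4) for i in range(48)]  # concordant
)
print(ConditionalLogit(sets).fit().summary())
```

```
Conditional logistic regression (1 case : M controls, single binary exposure)
==============================================================================
Matched sets: 60   informative: 12   controls: 240
Exposed cases: 9/60   exposed controls: 3/240
log OR (beta):  2.4849   SE: 0.6667   iterations: 6
OR: 12.000   95% CI: (3.249, 44.325)
==============================================================================
```

A `prodroma` console script exposes the same stages for shell use
(`simulate`, `build-cohort`, `features`, `fit`, `report`, `run`); every
command is a thin wrapper over the functions above and chains on plain CSV
files.

## Input format

Two CSVs with ISO-8601 dates (see `prodroma.records`):

- `patients.csv`: `patient_id,sex,birth_date,practice_id,registration_start,registration_end,as_diagnosis_date,first_dmard_date` (last three optional);
- `events.csv`: `patient_id,date,category,event_type`.

Event categories are a closed 25-label vocabulary (`prodroma.vocabulary`):
spinal symptoms/diagnoses, AS-related musculoskeletal features, related
disorders, diagnostic tests and treatments.  Mapping a clinical coding
terminology (Read/SNOMED) onto these categories is the user's
responsibility and is deliberately outside the package.

See `docs/methods.md` for the statistical model, the synthetic-data
generator's assumptions and the package's design decisions.
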