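# Methods

This note records the analytic conventions, the generative model behind the
synthetic cohort, the numerical choices, and the known limitations of
`husegment`. Everything stated here is what the code computes; no empirical
claim is made beyond what the test suite and `scripts/acceptance.py`
themselves produce.

## Cohort construction

- **Index visit**: the earliest admission date per patient inside the
  half-open enrolment window `[study_start, study_end)` (defaults
  2006-01-01 to 2013-01-01, so the last qualifying day is 2012-12-31).
- **Observation years**: fixed-length 365-day half-open windows anchored at
  the index date, with no leap-day special-casing. Fixed-length windows make
  year-1/year-2 comparisons commensurable across patients; the residual
  ±1-day calendar drift is irrelevant at the aggregation level used here.
- **Inclusion**: age ≥ 21 completed calendar years at the index date.
  Possessing an index visit implies "at least one record"; therapy-only
  patients qualify.
- **Attribution**: a visit belongs to the window containing its admission
  date. Boundary-spanning inpatient stays contribute their full cost and LOS
  to that window, without proration — the simplest reproducible rule; it is
  recorded in the run manifest.
- **Metrics per patient-year**: cost sums billed charges over *all* visit
  types (therapy contributes cost only); admissions count inpatient visits
  including short stays; LOS sums `max(discharge − admission, 1)` days over
  non-short-stay admissions (so a same-day non-short stay counts 1 day, and
  no admitted patient has LOS 0); SOC and ED visits are counted per setting.
  Short stays (day surgery / endoscopy) are flagged in the data and excluded
  from LOS, following the OECD convention of dropping short-term treatments;
  whether they should also be excluded from the admissions count is
  ambiguous — we count them, and the manifest says so.

## Segmentation

- **Thresholds**: cohort 90th percentiles of cost and SOC over all included
  patients, and of LOS over admitted patients only. The percentile estimator
  is linear interpolation between order statistics at rank `1 + (n−1)q`
  (numpy's default); a nearest-rank switch exists for sensitivity analyses.
  The estimator choice is recorded in the manifest.
- **Exceedance is strict** (`> threshold`). Patients at or below all three
  thresholds are Non-HU; ties are folded into Non-HU deliberately, since
  with heavily discrete metrics (SOC counts) a `≥` rule would reclassify the
  whole modal bin.
- Never-admitted patients carry LOS 0 and are compared against the LOS
  threshold like everyone else; under strict exceedance they can never
  qualify, so treating their LOS as missing would change nothing.
- Thresholds are computed on the full included year-1 cohort, including
  patients who die during year 1, because group profiles report deaths
  within groups.
- **Persistence**: year-2 aggregates are classified against the *frozen*
  year-1 thresholds; zero-utilization patients are Non-HU in year 2 by
  construction; year-1 decedents carry no persistence label (NA).

## Comorbidity and conditions

- **CCMI** uses the 17-category Quan ICD-10 coding algorithm with the
  original Charlson weights (1/2/3/6), shipped as an editable CSV and
  unit-tested against hand-computed scores. Mild/severe hierarchy pairs
  (liver disease; diabetes ± chronic complication; malignancy / metastatic
  solid tumour) score only the severe member. CCMI is computed from year-1
  primary diagnoses — the only diagnosis field the data model carries; the
  lookback is recorded in the manifest. Missing CCMI is 0 downstream.
- **PPS** is the maximum number of unique dispensed medications in any
  single visit, over all loaded visits ("ever"); a window-restricted variant
  is available.
- **CCS grouping** maps each primary diagnosis to a reporting category via a
  user-loadable prefix mapping; unmapped codes fall into
  "Residual codes; unclassified". The packaged crosswalk is a small toy
  subset for the bundled examples; real analyses must load the official
  crosswalk.

## Group profiles

Medians and quartiles use the same order-statistic interpolation as the
thresholds. Every percentage in a group column uses the group size N as the
denominator, decedents included. The treatment tier is derived per patient
from per-visit subsidy flags (all / none / mixed → subsidised-only /
unsubsidised-only / both). Top-5 condition lists are ranked by patients-ever
or by visit frequency; ties break lexicographically by label so outputs are
deterministic. Percentages print at 1 decimal with half-up rounding (the
convention the bundled reference tables follow); money at whole S$.

## Persistence models

- Design: exclusions are year-1 death and missing gender/race/nationality;
  unknown housing is its own level (mirroring the "Unknown" housing row in
  the reference tables) rather than a missingness exclusion. Reference
  levels: Non-HU, female, chinese, foreigner, subsidised-only, 1/2-room
  rental.
- Fitting: IRLS (statsmodels GLM, binomial family) with deviance tolerance
  1e-8 and at most 100 iterations. Collinear columns are dropped with a
  warning. Complete separation and non-convergence raise an explicit error
  naming the offending term; *quasi*-separation (a zero cell in a small
  dummy level) completes with a warning and an unreliable OR for that level,
  matching the behaviour of standard GLM implementations. In small
  simulated cohorts the rare LOS-type groups can have single-digit sizes, so
  this case is reachable and deliberately non-fatal.
- **Backward elimination** tests each removable factor with all of its dummy
  columns jointly by likelihood-ratio test against the current model,
  removes the worst factor with p ≥ 0.001, refits, and repeats; per-level
  Wald removal would fragment categorical factors, so the joint test is the
  default and a Wald switch exists for sensitivity. The HU-group exposure is
  never eliminated. Model 2 starts from Model 1's surviving factors plus the
  condition indicators, and its elimination applies only to the newly added
  condition indicators — the Model 1 adjustments are carried forward. This
  keeps Model 1 nested in Model 2, so the likelihood-ratio test between them
  is well-defined (re-eliminating Model 1's factors can otherwise remove one
  and break nesting).
- 99% Wald CIs on the log-odds scale; McFadden's R² against the
  intercept-only log-likelihood (closed form); LRTs between Models 0/1 and
  1/2 use the same observations by construction.

## Synthetic cohort generator

The generator emulates the joint structure the analysis needs, not any real
hospital's joint distribution:

- **Archetypes** (defaults): routine low use (mix 0.787), cardiac one-off
  (0.05), frail elderly multimorbid (0.04), psychiatric long stay (0.025),
  high-SOC ambulatory (0.098). Each sets per-year rates for admissions /
  SOC / ED / therapy, a log-normal LOS, log-normal per-visit cost with an
  inpatient multiplier and a `LOS^0.8` coupling, a diagnosis pool, a
  medication-count range, year-1 death hazard, an age distribution, and a
  gender mix. The defaults were fixed once, to reproduce the qualitative
  pattern the analysis expects at the simulation scales used here
  (n ≈ 20,000): a dominant Non-HU segment holding a minority of cost, a
  cheap-but-long-stay psychiatric segment, an expensive frail-elderly
  segment with high mortality, and every HU group populated well enough for
  the group factor to be estimable. They are not a quantitative fit to any
  real cohort.
- **Counts**: per setting and year, Poisson given `rate × frailty`, with a
  patient-level gamma frailty of mean 1 shared across both years — i.e.
  negative-binomial marginals with cross-year persistence correlation from
  the shared frailty. The gamma shape solves
  `trigamma(k) = frailty_sd²` (inverse trigamma via Brent), so `frailty_sd`
  keeps its meaning as the SD of log-frailty.
- **Year-2 dynamics**: each patient's utilization process stays active in
  year 2 with an archetype-specific probability (`year2_activity`); dormant
  patients drop to 15% of their year-1 rates. This is the episodic-care
  mechanism that produces the regression-to-the-mean behaviour real HU
  cohorts show (most HUs do not persist); routine low use is always active.
  `plant_persistence` multiplies an archetype's year-2 rates by a given
  factor, which raises its threshold-exceedance odds monotonically — the
  map from rate scale to odds depends on the frozen empirical thresholds,
  so planted factors are recovered as an *ordering* of group odds ratios,
  not as exact OR values.
- **Details**: LOS is discretised log-normal with a 1-day floor; a
  configurable fraction of admissions are same-day short stays; the earliest
  year-1 visit is anchored at the entry date so the generative and analytic
  windows coincide; deaths are a single Bernoulli draw in year 1 with a
  uniform death date truncating later visits; each patient's subsidy tier
  (always / never / mixed subsidised) drives the per-visit flags.
- Identical (config, seed) pairs produce byte-identical CSVs.

**What passing tests do and do not show.** The generator produces the
skewed costs, heavy-tailed LOS, archetype-specific diagnosis mixes,
mortality, and persistence correlation the method assumes — so green tests
demonstrate the pipeline's correctness and the method's behaviour under
those assumptions. Real data add features the generator omits (seasonality,
coding drift, transfers and cross-cluster utilization, informative missingness,
within-year disease progression), so test results do not certify performance
on any particular real cohort.

## Problem sizes

Unit tests run on cohorts of tens to a few thousand patients. The
Monte-Carlo suites use 100 replicates at n = 5,000 for the elimination-level
check, 50 replicates at n = 20,000 for planted-persistence ordering
recovery, and a 2,500-patient double run for byte-level determinism; the
acceptance script's headline run uses one 20,000-patient cohort. These sizes
give stable estimates for every populated group while keeping a full run on
one CPU in minutes.

## Known limitations

- The LOS-only and LOS-SOC segments are intrinsically rare; at n ≈ 20,000
  they may contain a handful of patients, and their ORs are then unstable
  (flagged as quasi-separation warnings).
- Housing type is an SES proxy taken as an input field; no postal-code
  derivation is attempted. Subsidy tiers come only from per-visit flags.
- Diagnosis codes are opaque strings; no ICD version is assumed and no
  ICD-9↔10 conversion is performed.
- Costs are assumed already inflation-adjusted; no adjustment is applied.
- No clustering-based segmentation, no ED-count HU criterion, and no
  survival or multilevel modelling.
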