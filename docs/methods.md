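# Methods

## Model structure and assumptions

The analysis compares two strategies for hospitalized COVID-19 patients —
PCT tested at baseline versus not — on observational, propensity-weighted
patient-level data. Year 1 after admission is an individual-level
decision-tree phase: each patient's observed ward days, ICU days, antibiotic
days, PCT tests and survival time determine their QALYs and costs directly,
so the "tree" is parameterized by the data rather than by branch-level
expected values. Patients alive at 365.25 days enter a cohort Markov phase
with two states (alive, dead), annual cycles, age/sex life-table mortality
and age/sex population-norm utilities, discounted at 3% per year. Costs are
confined to year 1; the Markov phase accrues QALYs only, so the incremental
cost is identical under the 1-year and lifetime horizons.

Key structural assumptions:

- **Additive, overlapping decrements.** Ward, ICU and antibiotic utility
  decrements subtract independently from baseline utility
  (days × decrement / 365.25); a day in ICU on antibiotics incurs both. The
  resulting `qalys_dt` may be negative for very long stays.
- **Full decrement regardless of survival.** The decrement term is not
  truncated at death; the alive-time term alone scales with survival. This
  matches the published column arithmetic, where each QALY-loss column equals
  mean days × decrement / 365.25 unconditionally.
- **No discounting within year 1**; discounting starts at the first Markov
  cycle. No half-cycle correction by default (`half_cycle_correction`
  enables the standard mean-of-adjacent-survival variant).
- **In-hospital death** is identified by survival time equal to (not
  exceeding) the derived total stay.
- **Transition-probability convention.** In-hospital death is reported
  unconditionally; death before 1 year / Markov entry are conditional on
  discharge. The source tables are internally inconsistent on this point
  (the conditional Markov-entry probability equals the reported
  unconditional 1-year survival); we use the conditional reading, so the
  pipeline's unconditional 1-year survival is the product of the discharge
  and Markov-entry probabilities (≈ 0.43), not 0.615.

## Parameters

| Parameter | Default | Unit | Notes |
|---|---|---|---|
| Ward utility decrement | 0.36 | /day | literature value |
| ICU utility decrement | 0.58 | /day | literature value |
| Antibiotic utility decrement | 0.05 | /day | complication risk proxy |
| Ward cost | 487.50 × 1.025 | £/day | 2.5% inflation uplift |
| ICU cost | 2386 | £/day | reference cost |
| PCT test cost | 15.20 | £/test | list price incl. overheads, uplifted |
| AMR cost | 2.12 | £/prescription | `amr_unit` switch: per record (default) or per dose |
| Discount rate | 0.03 | /year | Markov utilities only |
| Decision-tree horizon | 365.25 | days | |
| Markov terminal age | 110 | years | life table forces q = 1 |
| WTP threshold grid | 0–50 000 (step 500) | £/QALY | CEAC support |
| Bootstrap iterations | 100 000 | — | tests/examples use ~2000 |

The published ward per-diem is internally inconsistent with the published
mean ward costs (which imply ≈ £400/day); we keep the stated per-diem and do
not treat ward-cost levels as a reproduction target.

## Synthetic cohort: what it emulates, what it does not

The generator reproduces the statistical structure the analysis depends on,
calibrated so arm-level expectations match the published group summaries:

- arm assignment Bernoulli(0.26);
- ward days negative-binomial (size 0.5 — long right tail; the source
  reports no dispersion, so this is a judgement call exposed in config),
  arm means 9.28 / 10.7;
- ICU stays zero-inflated gamma rounded to whole days; P(any ICU) = 0.17
  (not reported in the source; chosen as a realistic first-wave ICU
  admission fraction) with conditional mean `mean_icu_days / p_icu`;
- antibiotic exposure as 1–4 sequential courses partitioning a
  negative-binomial total (arm means 5.94 / 6.78 days), with free-text names
  corrupted by case changes, whitespace, truncations, single-character typos
  and ward shorthand, and ~2.7% of records made uncostable to mirror the
  reported 97.3% costing coverage;
- in-hospital death Bernoulli per arm (0.309 / 0.301) setting survival to
  the end of stay; post-discharge death Bernoulli conditional on discharge
  (0.385 / 0.395) uniform on (discharge, day 365); survivors censored at 366;
- PSM weights Gamma(4) scaled to mean 1 — positive and right-skewed,
  standing in for weights an upstream matching analysis would supply;
- age N(70, 16) truncated to [16, 100], 56% male; ethnicity, deprivation
  decile and comorbidity counts are generated but cosmetic.

Not emulated: age- or severity-dependent mortality (deaths are exchangeable
within arm, so synthetic 1-year survivors have the same age distribution as
decedents; real survivors skew younger, which is the main reason synthetic
lifetime QALYs (~4) sit below the published ~8.7); between-site
heterogeneity; correlation between stay length and mortality; seasonal
admission structure. Passing tests therefore demonstrate correctness of the
*pipeline arithmetic and estimators* under the stated data-generating
process, not reproduction of the headline cohort results, which depend on
the non-public records.

## Costing details

Free-text normalization lower-cases, collapses whitespace, then applies the
ordered rule table (first match wins; blocked terms are non-antibiotics).
Unmatched text is recovered against the 27-drug lexicon by unique prefix
(≥ 4 characters) and then unique edit-distance-1 neighbour; anything else is
`unrecognized` and counted as an uncosted antibiotic record — never silently
zero-priced. Dose parsing folds unit synonyms (mg/g/millilitres/units/IU)
and converts grams to mg. Price matching searches the primary tier before
the indicative tier; within a tier an exact dose match (cheapest if
several) beats a multiple match, which uses the smallest integer k ≥ 2 with
k × listed dose = prescribed dose, ties broken by lowest cost. Antibiotic
records carry durations rather than calendar dates, so days on treatment are
summed per record; the generator emits non-overlapping sequential courses,
making that sum equal the calendar-day union that the antibiotic decrement
conceptually applies to. The bundled price table and rule file are editable
synthetic fixtures, not extracts of the versioned national sources.

## Estimation and uncertainty

Group summaries are weighted means Σwᵢxᵢ/Σwᵢ. The bootstrap resamples
patients with replacement within each arm at its original size (realized as
multinomial resampling counts so weighted means become chunked matrix
products), carrying weights, and recomputes all summary columns per
iteration; 95% CIs are the 2.5/97.5 percentiles. ICER CIs are percentile
intervals of the draw-wise ratio and are descriptive only when the draws
span quadrants. CEAC values count strict net-monetary-benefit inequalities
(ties → not cost-effective, measure-zero for continuous data). A pooled
(cross-arm) resampling switch is not provided; the matched-then-bootstrap
design resamples individuals within arm. The robustness path removes
patients whose general-ward stay covers the whole decision-tree year
(ward_days ≥ 365.25) before re-running the analysis.

## QC and exclusions

Total stay = discharge − max(positive-test day, admission day); ICU stay =
ICU out − max(positive-test day, ICU in); ward = total − ICU. Negative
derived stays are treated as the corresponding missing-LOS class. Exclusion
rules apply in a fixed order (missing ICU LOS, missing total LOS, missing
survival, ICU > total, total > survival) with each patient attributed to the
first matching rule; because the source's per-rule counts do not sum to its
total exclusions (implying overlap), the log also records any-match counts
per rule.

## Numerical choices and problem sizes

Day offsets are 0-based integers; differences are exclusive of the start
day (same-day admission/discharge = 0 days). All randomness flows from one
root seed split by `numpy.random.SeedSequence` (cohort, bootstrap); derived
seeds stay below 2³¹. Dose-multiple matching uses a 10⁻⁹ relative
tolerance. Validation of parameter containers is by pydantic, erroring on
the offending field. Tests and the acceptance script use cohorts of
n = 5000 and ~2000 bootstrap iterations — sizes at which the calibration
targets are recovered within 3 standard errors while the whole suite runs in
well under a minute; the 100 000-iteration default matches the published
analysis and is intended for real runs.

## Known limitations

- Lifetime QALY levels depend on the synthetic life table and norms and on
  age-independent synthetic mortality; they are qualitative, not
  reproductions (see above).
- Free-text frequency parsing is out of scope: `frequency_per_day` must be
  an integer field.
- No parametric sensitivity analysis over the unit-cost/decrement
  parameters; uncertainty is bootstrap-only, as in the source analysis.
- No modelling of readmission, long-COVID morbidity, or health effects of
  antimicrobial resistance (cost only).
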