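# peach-cea

Cost-effectiveness analysis of baseline procalcitonin (PCT) testing for
guiding antibiotic prescribing in patients hospitalized with COVID-19.

During the first pandemic wave many UK hospitals introduced PCT — a blood
biomarker of bacterial infection — to decide which COVID-19 inpatients should
receive antibiotics. This package implements the full health-economic
pipeline needed to ask whether testing PCT at baseline was worth paying for:
patient-level quality-adjusted life years (QALYs) and costs over a 1-year
decision-tree phase, a lifetime alive/dead Markov phase for 1-year survivors,
and a weighted bootstrap to characterize decision uncertainty. It is aimed at
health economists and methodologists who want a tested, reusable, fully
synthetic-data-compatible implementation of this class of two-phase
cost-effectiveness model.

## The model

For patient *i* with propensity-score-matching weight *w_i*, year-1 QALYs are

```
QALY_dt(i) = u0(age_i, sex_i) · min(surv_i, 365.25)/365.25
             − (ward_i·0.36 + icu_i·0.58 + abx_i·0.05)/365.25
```

where `u0` is the age/sex population-norm utility and the per-day decrements
(general ward −0.36, ICU −0.58, antibiotics −0.05) are additive and may
overlap. Year-1 costs are

```
C(i) = ward_i·£499.69 + icu_i·£2386 + pct_i·£15.20 + C_drugs(i) + 2.12·n_rx(i)
```

with the ward per-diem £487.50 uplifted 2.5% for inflation, drug costs from a
two-tier unit-price table (market tier preferred, indicative tier fallback,
prescribed doses matched exactly or as the smallest integer multiple of a
listed dose), and £2.12 per prescription as the expected future cost of
antimicrobial resistance. Patients alive at 1 year enter a Markov phase with
annual cycles k = 1, 2, …:

```
QALY_markov = Σ_k S_k · u0(age+k, sex) · (1.03)^(−k),   S_k = Π_j (1 − q(age+j, sex))
```

with life-table mortality `q` and utilities discounted at 3%/year; no costs
accrue after year 1. Incremental QALYs ΔE and costs ΔC between the
baseline-PCT and no-baseline-PCT arms come from weighted arm means; a
within-arm patient bootstrap (default 100 000 iterations) yields percentile
CIs, the cost-effectiveness plane, the ICER ΔC/ΔE with its dominance
quadrant, and cost-effectiveness acceptability curves
P(λ·ΔE − ΔC > 0) over thresholds λ ∈ [£0, £50 000].

Because the underlying NHS records are not public, the package ships a
calibrated synthetic-cohort generator (`peach_cea.synthetic_cohort`) that
emulates their structure — long-tailed ward/ICU stays, arm-specific mortality,
messy free-text antibiotic prescriptions, positive matching weights — plus a
QC stage implementing the published derivation and exclusion rules, and
free-text antibiotic normalization with typo/shorthand recovery. The bundled
life table, utility norms and price table are synthetic fixtures with
realistic shape (see `docs/methods.md`).

## Worked example

```python
from peach_cea import (CohortGenParams, generate_cohort, apply_exclusions,
                       EconParams, compute_outcomes,
                       estimate_transition_probabilities, run_cea)
from peach_cea.abx_costing import (cost_antibiotics, load_default_rules,
                                   load_default_price_table)
from peach_cea.econ_model import (load_default_life_table,
                                  load_default_utility_norms)

cohort = generate_cohort(CohortGenParams(n_patients=5000, seed=1))
clean, log = apply_exclusions(cohort)
rules, prices = load_default_rules(), load_default_price_table()
costed = [cost_antibiotics(p.antibiotic_records, rules, prices) for p in clean]
outcomes = compute_outcomes(clean, costed, EconParams(),
                            load_default_utility_norms(),
                            load_default_life_table())
print(estimate_transition_probabilities(outcomes).round(3).to_string(index=False))
res = run_cea(outcomes, B=2000, seed=2, thresholds=EconParams().thresholds())
print(f"dQALY (lifetime) = {res.de_lifetime:+.4f}   dCost = {res.dc:+.0f} GBP")
print(f"ICER (lifetime) = {res.icer_lifetime:,.0f} GBP/QALY [{res.icer_lifetime_label}]")
print(f"P(cost-effective at 20k GBP/QALY): {res.p_cost_effective(20000):.3f}")
```

prints

```
            arm  p_hospitalized_dead  p_hospitalized_discharged  p_discharged_dead  p_discharged_markov
   baseline_pct                0.285                      0.715              0.383                0.617
no_baseline_pct                0.322                      0.678              0.380                0.620
dQALY (lifetime) = +0.1104   dCost = -782 GBP
ICER (lifetime) = -7,077 GBP/QALY [dominant]
P(cost-effective at 20k GBP/QALY): 0.760
```

The transition probabilities recover the generator's calibration (baseline-PCT
in-hospital death 0.309, 1-year survival given discharge 0.615) within
Monte-Carlo error. Baseline PCT testing gains QALYs and saves money in this
draw — a negative ICER in the dominant quadrant — but with the decision
uncertainty visible in the acceptability probability.

The same pipeline is available from the shell:

```
peach-cea simulate --n 5000 --seed 1 --out sim/
peach-cea run --seed 1 --bootstrap 2000 --out run/
peach-cea report --run-dir run/
```

`run/` then contains the transition, summary and acceptability tables as CSV
(`transition_table3.csv`, `summary_table4.csv`, `summary_table5.csv`,
`ceac.csv`), the cost-effectiveness-plane draws, the exclusion log, robustness
variants with full-year ward-stay outliers removed (`*_robust.csv`), and a
manifest sufficient to reproduce the run byte-for-byte.

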