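"""Seeded synthetic cohorts of hospitalized COVID-19 patients.

The real analysis ran on undeposited NHS patient-level records.  This module
generates cohorts with the same statistical structure so the downstream
pipeline (QC, costing, economic model, bootstrap) can be exercised and
validated end to end: two arms distinguished by baseline procalcitonin (PCT)
testing, long-tailed ward and ICU lengths of stay, in-hospital and
post-discharge mortality, messy free-text antibiotic prescriptions, and
positive propensity-score-matching weights.

Default calibration targets the published group summaries: 26% of patients
PCT-tested at baseline; arm mean ward stays 9.28/10.7 days, ICU stays
2.55/2.68 days, antibiotic days 5.94/6.78, PCT test counts 2.24/0.694;
in-hospital death probabilities 0.309/0.301 and 1-year post-discharge death
probabilities 0.385/0.395; age ~ N(70, 16) truncated to [16, 100] with 56%
male.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .abx_costing import load_default_rules, load_default_price_table

__all__ = [
    "ArmParams",
    "CohortGenParams",
    "QCViolationRates",
    "RawAbxRecord",
    "RawPatientRecord",
    "generate_cohort",
    "corrupt_abx_name",
    "inject_qc_violations",
    "ABX_SHORTHAND",
]

# Canonical -> common ward shorthand; every entry round-trips through the
# bundled normalization rules.
ABX_SHORTHAND = {
    "amoxicillin": "amox",
    "co-amoxiclav": "co-amox",
    "piperacillin-tazobactam": "tazocin",
    "flucloxacillin": "fluclox",
    "ciprofloxacin": "cipro",
    "clarithromycin": "clari",
    "metronidazole": "metro",
    "vancomycin": "vanc",
    "gentamicin": "gent",
    "doxycycline": "doxy",
    "azithromycin": "azithro",
    "benzylpenicillin": "benpen",
    "co-trimoxazole": "septrin",
    "meropenem": "mero",
    "teicoplanin": "teic",
    "erythromycin": "erythro",
    "trimethoprim": "trimeth",
}

_ETHNICITIES = ("white", "black", "asian", "mixed", "other")
_ETHNICITY_P = (0.79, 0.04, 0.07, 0.01, 0.09)


class ArmParams(BaseModel):
    """Per-arm calibration constants for the generator."""

    mean_ward_days: float = Field(ge=0)
    mean_icu_days: float = Field(ge=0)
    p_icu: float = Field(ge=0, le=1)
    mean_abx_days: float = Field(ge=0)
    mean_pct_tests: float = Field(ge=0)
    p_hospital_death: float = Field(ge=0, le=1)
    p_postdischarge_death_1y: float = Field(ge=0, le=1)


class CohortGenParams(BaseModel):
    """Full parameterization of a synthetic cohort; defaults are the study
    calibration (see module docstring)."""

    n_patients: int = Field(ge=2)
    seed: int = 0
    p_baseline_pct: float = Field(default=0.26, ge=0, le=1)
    baseline_pct: ArmParams = ArmParams(
        mean_ward_days=9.28,
        mean_icu_days=2.55,
        p_icu=0.17,
        mean_abx_days=5.94,
        mean_pct_tests=2.24,
        p_hospital_death=0.309,
        p_postdischarge_death_1y=0.385,
    )
    no_baseline_pct: ArmParams = ArmParams(
        mean_ward_days=10.7,
        mean_icu_days=2.68,
        p_icu=0.17,
        mean_abx_days=6.78,
        mean_pct_tests=0.694,
        p_hospital_death=0.301,
        p_postdischarge_death_1y=0.395,
    )
    age_mean: float = Field(default=70.0, gt=0)
    age_sd: float = Field(default=16.0, ge=0)
    p_male: float = Field(default=0.56, ge=0, le=1)
    # dispersion of the stay distributions (judgement calls; not reported for
    # the source cohort): negative-binomial size for ward days / antibiotic
    # days, gamma shape for the conditional ICU stay
    ward_nb_size: float = Field(default=0.5, gt=0)
    abx_nb_size: float = Field(default=1.0, gt=0)
    icu_gamma_shape: float = Field(default=0.8, gt=0)
    weight_gamma_shape: float = Field(default=4.0, gt=0)
    text_corruption_rate: float = Field(default=0.3, ge=0, le=1)
    p_uncostable_record: float = Field(default=0.027, ge=0, le=1)

    @model_validator(mode="after")
    def _icu_consistent(self):
        for name in ("baseline_pct", "no_baseline_pct"):
            arm = getattr(self, name)
            if arm.mean_icu_days > 0 and arm.p_icu == 0:
                raise ValueError(f"{name}.p_icu is 0 but mean_icu_days > 0")
        return self

    def arm(self, arm_name: str) -> ArmParams:
        return self.baseline_pct if arm_name == "baseline_pct" else self.no_baseline_pct


@dataclass(frozen=True)
class RawAbxRecord:
    """One antibiotic course as captured in prescribing free text."""

    name_text: str
    dose_text: str
    frequency_per_day: int
    days: int


@dataclass(frozen=True)
class RawPatientRecord:
    """One patient as extracted from hospital records, before QC.

    Day fields are 0-based integer offsets from an arbitrary epoch; only
    differences are meaningful.  Any day offset and ``survival_days`` may be
    missing (``None``).
    """

    patient_id: str
    arm: str  # baseline_pct | no_baseline_pct
    age: float
    sex: str  # male | female
    psm_weight: float
    admission_day: Optional[int]
    covid_test_day: Optional[int]
    discharge_day: Optional[int]
    icu_in_day: Optional[int]
    icu_out_day: Optional[int]
    survival_days: Optional[float]
    pct_test_count: int
    antibiotic_records: tuple = ()
    ethnicity: str = "white"
    imd_decile: int = 5
    n_comorbidities: int = 2


# ---------------------------------------------------------------------------
# free-text corruption


def _corrupt_name(name: str, rate: float, rng: np.random.Generator) -> str:
    if rng.random() >= rate:
        return name
    kinds = ["case", "whitespace", "truncate", "typo"]
    if name in ABX_SHORTHAND:
        kinds.append("shorthand")
    kind = kinds[rng.integers(len(kinds))]
    if kind == "case":
        return name.upper() if rng.random() < 0.5 else name.title()
    if kind == "whitespace":
        return " " * int(rng.integers(1, 3)) + name + " " * int(rng.integers(1, 3))
    if kind == "truncate":
        lo = max(5, len(name) - 4)
        if lo >= len(name):
            return name.upper()
        keep = int(rng.integers(lo, len(name)))
        return name[:keep]
    if kind == "typo":
        pos = int(rng.integers(1, len(name)))
        letters = "abcdefghijklmnopqrstuvwxyz"
        repl = letters[rng.integers(26)]
        while repl == name[pos]:
            repl = letters[rng.integers(26)]
        return name[:pos] + repl + name[pos + 1 :]
    return ABX_SHORTHAND[name]


def corrupt_abx_name(canonical_name: str, rate: float, seed: int) -> str:
    """Return a deterministic corruption of a canonical antibiotic name.

    With probability ``rate`` applies one of: case change, padding whitespace,
    truncation, a single-character typo, or a known ward shorthand; otherwise
    returns the input unchanged.  Every corruption normalizes back to its
    source via :func:`peach_cea.abx_costing.normalize_abx_name` with the
    bundled rules.
    """
    lexicon = load_default_rules().lexicon
    if canonical_name not in lexicon:
        raise ValueError(f"{canonical_name!r} is not in the antibiotic lexicon")
    rng = np.random.default_rng(seed)
    return _corrupt_name(canonical_name, rate, rng)


# ---------------------------------------------------------------------------
# cohort generation


def _draw_negbin(rng: np.random.Generator, mean: float, size_param: float) -> int:
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def _dose_text(rng: np.random.Generator, dose_mg: float, uncostable: bool) -> str:
    if uncostable:
        return ["one tablet", "as directed", "stat dose"][rng.integers(3)]
    u = rng.random()
    if dose_mg % 1000 == 0 and u < 0.3:
        return f"{dose_mg / 1000:g} g"
    if u < 0.5:
        return f"{dose_mg:g}mg"
    if u < 0.6:
        return f"{dose_mg:g} milligrams"
    return f"{dose_mg:g} mg"


def _abx_records(
    rng: np.random.Generator,
    params: CohortGenParams,
    arm: ArmParams,
    drug_names: list,
    doses_by_drug: dict,
) -> tuple:
    total_days = _draw_negbin(rng, arm.mean_abx_days, params.abx_nb_size)
    if total_days == 0:
        return ()
    n_courses = min(1 + int(rng.poisson(0.8)), total_days)
    split = rng.multinomial(total_days - n_courses, [1.0 / n_courses] * n_courses) + 1
    records = []
    for days in split:
        drug = drug_names[rng.integers(len(drug_names))]
        doses = doses_by_drug[drug]
        dose = float(doses[rng.integers(len(doses))])
        # occasionally prescribe a multiple of a listed dose
        if rng.random() < 0.12:
            dose *= 2
        uncostable = rng.random() < params.p_uncostable_record
        records.append(
            RawAbxRecord(
                name_text=_corrupt_name(drug, params.text_corruption_rate, rng),
                dose_text=_dose_text(rng, dose, uncostable),
                frequency_per_day=int(rng.integers(1, 4)),
                days=int(days),
            )
        )
    return tuple(records)


def generate_cohort(params: CohortGenParams) -> list:
    """Generate ``params.n_patients`` raw patient records.

    Reproducible given ``params.seed``.  Arm assignment is
    Bernoulli(p_baseline_pct).  Ward days are negative-binomial; ICU stays are
    zero-inflated gamma rounded to whole days.  In-hospital death (with the
    arm's probability) sets survival to the end of the stay; post-discharge
    deaths within the first year fall uniformly between discharge and day 365;
    survivors are recorded as 366 days (a censoring placeholder past the
    1-year decision-tree horizon).
    """
    if not isinstance(params, CohortGenParams):
        raise TypeError("params must be a CohortGenParams")
    rng = np.random.default_rng(params.seed)
    lexicon = sorted(load_default_rules().lexicon)
    price_frame = load_default_price_table().frame
    doses_by_drug = {
        name: sorted(g["dose_value"].unique())
        for name, g in price_frame[price_frame["dose_unit"] == "mg"].groupby("canonical_name")
    }
    drug_names = [n for n in lexicon if n in doses_by_drug]

    cohort = []
    for i in range(params.n_patients):
        arm_name = "baseline_pct" if rng.random() < params.p_baseline_pct else "no_baseline_pct"
        arm = params.arm(arm_name)
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 16.0, 100.0))
        sex = "male" if rng.random() < params.p_male else "female"
        weight = float(rng.gamma(params.weight_gamma_shape, 1.0 / params.weight_gamma_shape))

        ward = _draw_negbin(rng, arm.mean_ward_days, params.ward_nb_size)
        if arm.p_icu > 0 and rng.random() < arm.p_icu:
            cond_mean = arm.mean_icu_days / arm.p_icu
            icu = int(round(rng.gamma(params.icu_gamma_shape, cond_mean / params.icu_gamma_shape)))
        else:
            icu = 0
        total = ward + icu

        admission = int(rng.integers(0, 120))
        test = max(0, admission + int(rng.integers(-1, 2)))
        start = max(test, admission)
        discharge = start + total
        if icu > 0:
            icu_in = start + int(rng.integers(0, ward + 1))
            icu_out = icu_in + icu
        else:
            icu_in = icu_out = None

        if rng.random() < arm.p_hospital_death:
            survival: Optional[float] = float(total)
        elif rng.random() < arm.p_postdischarge_death_1y:
            survival = float(rng.uniform(total, 365.0)) if total < 365 else 366.0
        else:
            survival = 366.0

        if arm_name == "baseline_pct" and arm.mean_pct_tests >= 1:
            pct_tests = 1 + int(rng.poisson(arm.mean_pct_tests - 1))
        else:
            pct_tests = int(rng.poisson(arm.mean_pct_tests))

        cohort.append(
            RawPatientRecord(
                patient_id=f"P{i:05d}",
                arm=arm_name,
                age=age,
                sex=sex,
                psm_weight=weight,
                admission_day=admission,
                covid_test_day=test,
                discharge_day=discharge,
                icu_in_day=icu_in,
                icu_out_day=icu_out,
                survival_days=survival,
                pct_test_count=pct_tests,
                antibiotic_records=_abx_records(rng, params, arm, drug_names, doses_by_drug),
                ethnicity=_ETHNICITIES[rng.choice(len(_ETHNICITIES), p=_ETHNICITY_P)],
                imd_decile=int(rng.integers(1, 11)),
                n_comorbidities=int(rng.poisson(2.0)),
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# QC-violation injection


class QCViolationRates(BaseModel):
    """Per-class injection probabilities for QC stress-testing."""

    missing_icu_los: float = Field(default=0.0, ge=0, le=1)
    missing_total_los: float = Field(default=0.0, ge=0, le=1)
    missing_survival: float = Field(default=0.0, ge=0, le=1)
    icu_gt_total: float = Field(default=0.0, ge=0, le=1)
    total_gt_survival: float = Field(default=0.0, ge=0, le=1)


def _start_day(rec: RawPatientRecord) -> int:
    days = [d for d in (rec.covid_test_day, rec.admission_day) if d is not None]
    return max(days) if days else 0


def inject_qc_violations(
    cohort: list,
    rates: QCViolationRates,
    seed: int,
) -> tuple[list, dict]:
    """Inject seeded QC violations into disjoint subsets of a cohort.

    Classes are drawn in the fixed order missing_icu_los, missing_total_los,
    missing_survival, icu_gt_total, total_gt_survival; a patient receives at
    most one violation, so the per-class tally returned alongside the edited
    cohort matches the downstream exclusion-log counts exactly.
    """
    rng = np.random.default_rng(seed)
    out = list(cohort)
    untouched = set(range(len(out)))
    tally = {name: 0 for name in QCViolationRates.model_fields}

    def _eligible_total(rec: RawPatientRecord) -> Optional[int]:
        if rec.discharge_day is None:
            return None
        return rec.discharge_day - _start_day(rec)

    for cls in tally:
        rate = getattr(rates, cls)
        if rate <= 0:
            continue
        for idx in sorted(untouched):
            rec = out[idx]
            total = _eligible_total(rec)
            if total is None or total < 0:
                continue
            if cls == "total_gt_survival" and (total < 1 or rec.survival_days is None):
                continue
            if rng.random() >= rate:
                continue
            if cls == "missing_icu_los":
                rec = dataclasses.replace(rec, icu_in_day=_start_day(rec), icu_out_day=None)
            elif cls == "missing_total_los":
                rec = dataclasses.replace(rec, discharge_day=None)
            elif cls == "missing_survival":
                rec = dataclasses.replace(rec, survival_days=None)
            elif cls == "icu_gt_total":
                excess = int(rng.integers(1, 6))
                rec = dataclasses.replace(
                    rec,
                    icu_in_day=_start_day(rec),
                    icu_out_day=rec.discharge_day + excess,
                )
            else:  # total_gt_survival
                rec = dataclasses.replace(rec, survival_days=total * float(rng.uniform(0.0, 0.8)))
            out[idx] = rec
            untouched.discard(idx)
            tally[cls] += 1
    return out, tally
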