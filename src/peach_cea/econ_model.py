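"""Two-phase health-economic model: decision-tree year plus lifetime Markov.

Year 1 after hospitalization is modelled at the individual level: each
patient accrues quality-adjusted life years (QALYs) as their baseline utility
(age/sex population norm) scaled by time alive in the year, minus additive
per-day utility decrements for general-ward days (0.36), ICU days (0.58) and
antibiotic days (0.05); costs accrue per ward day, ICU day, PCT test,
antibiotic dose, and a per-prescription antimicrobial-resistance surcharge.
Decrements are independent and may overlap (an ICU day on antibiotics incurs
both), and no discounting is applied within the first year.

Patients alive at one year enter an alive/dead Markov phase with annual
cycles: cycle survival follows age/sex life-table mortality, each cycle
contributes the attained-age utility norm discounted at 3% per year, and no
costs accrue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .abx_costing import AbxCostSummary
from .cohort_qc import PatientRecord

__all__ = [
    "EconParams",
    "LifeTable",
    "UtilityNorms",
    "PatientOutcome",
    "load_default_life_table",
    "load_default_utility_norms",
    "baseline_utility",
    "decision_tree_outcomes",
    "markov_lifetime_qalys",
    "compute_outcomes",
    "estimate_transition_probabilities",
]


class EconParams(BaseModel):
    """Economic parameters (defaults: published unit costs and decrements).

    ``c_ward_base`` carries a 2.5% inflation uplift to the costing year via
    ``ward_uplift``; the PCT unit cost is already uplifted.  All costs GBP.
    """

    u_ward_decrement: float = Field(default=0.36, ge=0, le=1)
    u_icu_decrement: float = Field(default=0.58, ge=0, le=1)
    u_abx_decrement: float = Field(default=0.05, ge=0, le=1)
    c_ward_base: float = Field(default=487.50, ge=0)
    ward_uplift: float = Field(default=0.025, ge=0)
    c_icu_per_day: float = Field(default=2386.0, ge=0)
    c_pct_per_test: float = Field(default=15.20, ge=0)
    c_amr_per_prescription: float = Field(default=2.12, ge=0)
    amr_unit: str = Field(default="per_record", pattern="^(per_record|per_dose)$")
    discount_rate: float = Field(default=0.03, ge=0, lt=1)
    days_per_year: float = Field(default=365.25, gt=0)
    dt_horizon_days: float = Field(default=365.25, gt=0)
    threshold_max: float = Field(default=50_000.0, ge=0)
    threshold_step: float = Field(default=500.0, gt=0)
    wtp_threshold: float = Field(default=20_000.0, ge=0)
    markov_max_age: int = Field(default=110, ge=1)
    half_cycle_correction: bool = False

    @property
    def c_ward_per_day(self) -> float:
        return self.c_ward_base * (1.0 + self.ward_uplift)

    def thresholds(self) -> np.ndarray:
        return np.arange(0.0, self.threshold_max + self.threshold_step / 2, self.threshold_step)


class LifeTable:
    """Annual death probabilities q(age, sex)."""

    def __init__(self, frame: pd.DataFrame):
        for col in ("age", "sex", "qx"):
            if col not in frame.columns:
                raise ValueError(f"life table missing column {col!r}")
        if ((frame["qx"] < 0) | (frame["qx"] > 1)).any():
            raise ValueError("qx must lie in [0, 1]")
        self._q = {
            sex: dict(zip(g["age"].astype(int), g["qx"].astype(float)))
            for sex, g in frame.groupby("sex")
        }

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def q(self, age: float, sex: str) -> float:
        try:
            return self._q[sex][int(age)]
        except KeyError:
            raise ValueError(f"life table has no entry for age {int(age)}, sex {sex!r}")

    @property
    def max_age(self) -> int:
        return max(max(ages) for ages in self._q.values())


class UtilityNorms:
    """Age-band x sex baseline utilities (population norms)."""

    EQ5D_MIN = -0.594

    def __init__(self, frame: pd.DataFrame):
        for col in ("age_low", "age_high", "sex", "utility"):
            if col not in frame.columns:
                raise ValueError(f"utility norms missing column {col!r}")
        if ((frame["utility"] < self.EQ5D_MIN) | (frame["utility"] > 1)).any():
            raise ValueError("utilities outside EQ-5D-consistent bounds")
        self._bands = {
            sex: sorted(
                (int(r.age_low), int(r.age_high), float(r.utility))
                for r in g.itertuples(index=False)
            )
            for sex, g in frame.groupby("sex")
        }

    @classmethod
    def from_csv(cls, path) -> "UtilityNorms":
        return cls(pd.read_csv(path))

    def lookup(self, age: float, sex: str) -> float:
        """Band lookup with nearest-band fallback below the bottom / above the
        top of the table."""
        try:
            bands = self._bands[sex]
        except KeyError:
            raise ValueError(f"utility norms have no entries for sex {sex!r}")
        if age < bands[0][0]:
            return bands[0][2]
        for lo, hi, u in bands:
            if lo <= age <= hi:
                return u
        return bands[-1][2]


def _open_data(name: str):
    from importlib import resources

    return resources.files("peach_cea.data").joinpath(name).open()


def load_default_life_table() -> LifeTable:
    """Bundled synthetic life table (national-life-table shape, not ONS data)."""
    with _open_data("life_table_synthetic.csv") as fh:
        return LifeTable.from_csv(fh)


def load_default_utility_norms() -> UtilityNorms:
    """Bundled synthetic utility norms (UK population-norm shape)."""
    with _open_data("utility_norms_synthetic.csv") as fh:
        return UtilityNorms.from_csv(fh)


def baseline_utility(age: float, sex: str, norms: UtilityNorms) -> float:
    """Baseline utility from population norms; cohort entry requires age >= 16."""
    if age < 16:
        raise ValueError(f"age {age} below the adult cohort minimum of 16")
    return norms.lookup(age, sex)


@dataclass(frozen=True)
class PatientOutcome:
    """Per-patient QALYs and itemized costs for both model phases."""

    patient_id: str
    arm: str
    qalys_dt: float
    qalys_markov: float
    cost_ward: float
    cost_icu: float
    cost_pct: float
    cost_drugs: float
    cost_amr: float
    alive_at_1y: bool

    @property
    def qalys_total(self) -> float:
        return self.qalys_dt + self.qalys_markov

    @property
    def cost_total(self) -> float:
        return self.cost_ward + self.cost_icu + self.cost_pct + self.cost_drugs + self.cost_amr


def decision_tree_outcomes(
    patient: PatientRecord,
    costed: AbxCostSummary,
    params: EconParams,
    norms: UtilityNorms,
) -> PatientOutcome:
    """Year-1 QALYs and costs for one cleaned patient (Markov part zero).

    QALYs: baseline utility scaled by the fraction of the year alive, minus
    (ward_days x 0.36 + icu_days x 0.58 + abx_days x 0.05) / 365.25.  Costs:
    per-day ward and ICU costs, per-test PCT cost, and the drug and
    antimicrobial-resistance costs from the costing stage.
    """
    u0 = baseline_utility(patient.age, patient.sex, norms)
    dpy = params.days_per_year
    t_alive = min(patient.survival_days, params.dt_horizon_days)
    decrement = (
        patient.ward_days * params.u_ward_decrement
        + patient.icu_days * params.u_icu_decrement
        + costed.abx_days * params.u_abx_decrement
    ) / dpy
    return PatientOutcome(
        patient_id=patient.patient_id,
        arm=patient.arm,
        qalys_dt=u0 * t_alive / dpy - decrement,
        qalys_markov=0.0,
        cost_ward=patient.ward_days * params.c_ward_per_day,
        cost_icu=patient.icu_days * params.c_icu_per_day,
        cost_pct=patient.pct_test_count * params.c_pct_per_test,
        cost_drugs=costed.total_drug_cost,
        cost_amr=costed.amr_cost,
        alive_at_1y=patient.survival_days > params.dt_horizon_days,
    )


def markov_lifetime_qalys(
    age_at_1y: float,
    sex: str,
    life_table: LifeTable,
    norms: UtilityNorms,
    params: EconParams,
) -> float:
    """Discounted lifetime QALYs from the Markov phase for a 1-year survivor.

    Annual cycles k = 1, 2, ...: survival to cycle k is the product of
    (1 - q) over attained ages, the cycle contributes survival x utility norm
    at the attained age x (1 + r)^(-k), until ``markov_max_age``.  With the
    half-cycle correction enabled, each cycle instead uses the mean of the
    start- and end-of-cycle survival.  No costs accrue in this phase.
    """
    total = 0.0
    surv_prev = 1.0
    max_age = params.markov_max_age
    k = 0
    while True:
        k += 1
        attained = age_at_1y + k
        if attained > max_age:
            break
        surv = surv_prev * (1.0 - life_table.q(age_at_1y + k - 1, sex))
        occupancy = 0.5 * (surv_prev + surv) if params.half_cycle_correction else surv
        total += occupancy * norms.lookup(attained, sex) * (1.0 + params.discount_rate) ** (-k)
        surv_prev = surv
        if surv <= 0.0:
            break
    return total


def compute_outcomes(
    patients: Iterable[PatientRecord],
    costed: Iterable[AbxCostSummary],
    params: EconParams,
    norms: UtilityNorms,
    life_table: LifeTable,
) -> pd.DataFrame:
    """Run both model phases for a cohort; returns one row per patient.

    Columns include the per-patient inputs (stays, tests, antibiotic days,
    weight), the year-1 and lifetime QALYs, and itemized + total costs.
    """
    rows = []
    for patient, cost in zip(patients, costed):
        out = decision_tree_outcomes(patient, cost, params, norms)
        q_markov = 0.0
        if out.alive_at_1y:
            q_markov = markov_lifetime_qalys(
                patient.age + 1.0, patient.sex, life_table, norms, params
            )
        rows.append(
            {
                "patient_id": patient.patient_id,
                "arm": patient.arm,
                "weight": patient.psm_weight,
                "age": patient.age,
                "sex": patient.sex,
                "ward_days": patient.ward_days,
                "icu_days": patient.icu_days,
                "abx_days": cost.abx_days,
                "pct_tests": patient.pct_test_count,
                "n_prescriptions": cost.n_prescriptions,
                "n_matched": cost.n_matched,
                "survival_capped": min(patient.survival_days, params.dt_horizon_days),
                "died_in_hospital": patient.died_in_hospital,
                "alive_at_1y": out.alive_at_1y,
                "baseline_utility": baseline_utility(patient.age, patient.sex, norms),
                "qaly_loss_ward": patient.ward_days * params.u_ward_decrement / params.days_per_year,
                "qaly_loss_icu": patient.icu_days * params.u_icu_decrement / params.days_per_year,
                "qaly_loss_abx": cost.abx_days * params.u_abx_decrement / params.days_per_year,
                "qalys_dt": out.qalys_dt,
                "qalys_markov": q_markov,
                "qalys_total": out.qalys_dt + q_markov,
                "cost_ward": out.cost_ward,
                "cost_icu": out.cost_icu,
                "cost_pct": out.cost_pct,
                "cost_drugs": out.cost_drugs,
                "cost_amr": out.cost_amr,
                "cost_total": out.cost_total,
            }
        )
    return pd.DataFrame(rows)


def estimate_transition_probabilities(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Weighted decision-tree transition probabilities per arm.

    Returns one row per arm with the unconditional probability of dying in
    hospital (and its complement, discharge) and, conditional on discharge,
    the probabilities of dying before 1 year versus surviving into the Markov
    phase.  Each branch pair sums to 1.
    """
    rows = []
    for arm, g in outcomes.groupby("arm"):
        if len(g) == 0 or g["weight"].sum() <= 0:
            raise ValueError(f"arm {arm!r} is empty or has zero total weight")
        w = g["weight"].to_numpy()
        died_hosp = g["died_in_hospital"].to_numpy(dtype=float)
        p_hosp_dead = float(np.average(died_hosp, weights=w))
        discharged = ~g["died_in_hospital"].to_numpy(dtype=bool)
        if discharged.sum() == 0:
            p_markov = np.nan
        else:
            wd = w[discharged]
            alive = g["alive_at_1y"].to_numpy(dtype=float)[discharged]
            p_markov = float(np.average(alive, weights=wd))
        rows.append(
            {
                "arm": arm,
                "p_hospitalized_dead": p_hosp_dead,
                "p_hospitalized_discharged": 1.0 - p_hosp_dead,
                "p_discharged_dead": 1.0 - p_markov,
                "p_discharged_markov": p_markov,
            }
        )
    return pd.DataFrame(rows)
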