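"""Decision-tree and Markov engine tests: closed-form oracles, published
unit-value arithmetic, and transition-probability estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_life_table
from peach_cea.abx_costing import AbxCostSummary
from peach_cea.cohort_qc import PatientRecord
from peach_cea.econ_model import (
    EconParams,
    UtilityNorms,
    baseline_utility,
    compute_outcomes,
    decision_tree_outcomes,
    estimate_transition_probabilities,
    markov_lifetime_qalys,
)


def patient(**kwargs):
    defaults = dict(
        patient_id="P1",
        arm="baseline_pct",
        age=70.0,
        sex="male",
        psm_weight=1.0,
        ward_days=9.0,
        icu_days=2.0,
        total_days=11.0,
        survival_days=366.0,
        died_in_hospital=False,
        pct_test_count=2,
    )
    defaults.update(kwargs)
    return PatientRecord(**defaults)


def costs(abx_days=0.0, drug=0.0, amr=0.0, n=0):
    return AbxCostSummary(
        total_drug_cost=drug,
        amr_cost=amr,
        coverage_fraction=1.0,
        abx_days=abx_days,
        n_prescriptions=n,
        n_matched=n,
    )


class TestBaselineUtility:
    def test_constant_norms(self, constant_norms):
        for age, sex in [(20, "male"), (70, "female"), (99, "male")]:
            assert baseline_utility(age, sex, constant_norms) == 0.8

    def test_age_below_16_rejected(self, norms):
        with pytest.raises(ValueError, match="16"):
            baseline_utility(12, "female", norms)

    def test_above_top_band_falls_back_to_top_band(self, norms):
        assert norms.lookup(200, "male") == norms.lookup(110, "male")

    def test_bundled_norms_decrease_with_age(self, norms):
        assert norms.lookup(20, "male") > norms.lookup(60, "male") > norms.lookup(90, "male")


class TestDecisionTree:
    def test_zero_stay_survivor_accrues_full_baseline_utility(self, constant_norms, econ):
        p = patient(ward_days=0.0, icu_days=0.0, total_days=0.0, pct_test_count=0)
        out = decision_tree_outcomes(p, costs(), econ, constant_norms)
        assert out.qalys_dt == pytest.approx(0.8)
        assert out.cost_total == 0.0
        assert out.alive_at_1y

    def test_cost_additivity_exact(self, constant_norms, econ):
        p = patient(ward_days=9.0, icu_days=2.0, pct_test_count=3)
        out = decision_tree_outcomes(p, costs(abx_days=5, drug=1.23, amr=4.24, n=2), econ, constant_norms)
        assert out.cost_total == out.cost_ward + out.cost_icu + out.cost_pct + out.cost_drugs + out.cost_amr

    def test_published_unit_value_arithmetic(self, constant_norms, econ):
        """Mean days x published decrement / 365.25 and mean counts x unit
        cost reproduce the published QALY-loss and cost columns."""
        p = patient(ward_days=9.28, icu_days=2.55, total_days=11.83, pct_test_count=0)
        out = decision_tree_outcomes(p, costs(abx_days=5.94), econ, constant_norms)
        ward_loss = 9.28 * 0.36 / 365.25
        assert ward_loss == pytest.approx(0.00915, rel=5e-3)
        icu_loss = 2.55 * 0.58 / 365.25
        abx_loss = 5.94 * 0.05 / 365.25
        expected_q = 0.8 * 1.0 - ward_loss - icu_loss - abx_loss
        assert out.qalys_dt == pytest.approx(expected_q, abs=1e-12)
        assert out.cost_icu == pytest.approx(2.55 * 2386)
        # PCT: weighted mean 2.24 tests x 15.20 GBP
        p2 = patient(ward_days=0, icu_days=0, total_days=0, pct_test_count=1)
        out2 = decision_tree_outcomes(p2, costs(), econ, constant_norms)
        assert 2.24 * out2.cost_pct == pytest.approx(34.10, rel=5e-3)

    @settings(max_examples=100, deadline=None)
    @given(
        ward=st.integers(0, 60),
        icu=st.integers(0, 30),
        abx=st.integers(0, 40),
        pct=st.integers(0, 6),
        survival=st.floats(0.0, 800.0, allow_nan=False),
    )
    def test_day_by_day_accumulation_oracle(self, constant_norms, econ, ward, icu, abx, pct, survival):
        """A per-day accumulation loop over the year reproduces the
        closed-form QALYs and costs to 1e-9."""
        survival = max(survival, float(ward + icu))
        p = patient(
            ward_days=float(ward),
            icu_days=float(icu),
            total_days=float(ward + icu),
            survival_days=survival,
            pct_test_count=pct,
        )
        out = decision_tree_outcomes(p, costs(abx_days=float(abx)), econ, constant_norms)
        dpy = econ.days_per_year
        t = min(survival, econ.dt_horizon_days)
        q = 0.0
        for _ in range(int(math.floor(t))):
            q += 0.8 / dpy
        q += 0.8 * (t - math.floor(t)) / dpy
        cost = 0.0
        for _ in range(ward):
            q -= econ.u_ward_decrement / dpy
            cost += econ.c_ward_per_day
        for _ in range(icu):
            q -= econ.u_icu_decrement / dpy
            cost += econ.c_icu_per_day
        for _ in range(abx):
            q -= econ.u_abx_decrement / dpy
        cost += pct * econ.c_pct_per_test
        assert out.qalys_dt == pytest.approx(q, abs=1e-9)
        assert out.cost_total == pytest.approx(cost, abs=1e-9)
        assert out.qalys_dt <= 0.8 + 1e-12


class TestMarkov:
    def test_certain_death_gives_zero_qalys(self, constant_norms, econ):
        lt = make_life_table({a: 1.0 for a in range(60, 111)})
        assert markov_lifetime_qalys(70, "male", lt, constant_norms, econ) == 0.0

    def test_annuity_closed_form(self, constant_norms, econ):
        """No mortality for 10 years then certain death: discounted annuity
        u x sum (1+r)^-k."""
        q = {a: 0.0 for a in range(70, 80)}
        q.update({a: 1.0 for a in range(80, 111)})
        lt = make_life_table(q)
        got = markov_lifetime_qalys(70, "male", lt, constant_norms, econ)
        expected = 0.8 * sum(1.03 ** (-k) for k in range(1, 11))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_geometric_series_closed_form(self, constant_norms):
        """Constant hazard, no discounting: u (1-q)/q (1 - (1-q)^N)."""
        params = EconParams(discount_rate=0.0, markov_max_age=110)
        qv = 0.1
        lt = make_life_table({a: qv for a in range(60, 110)} | {110: 1.0})
        age = 60
        N = 110 - age  # cycles until the table's terminal age
        got = markov_lifetime_qalys(age, "female", lt, constant_norms, params)
        expected = 0.8 * (1 - qv) / qv * (1 - (1 - qv) ** N)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_discounting_reduces_qalys_monotonically(self, constant_norms, life_table):
        vals = [
            markov_lifetime_qalys(70, "male", life_table, constant_norms, EconParams(discount_rate=r))
            for r in (0.0, 0.015, 0.03, 0.06)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(v >= 0 for v in vals)

    def test_half_cycle_correction_bounded_by_adjacent_estimates(self, constant_norms, life_table):
        plain = markov_lifetime_qalys(70, "male", life_table, constant_norms, EconParams())
        hcc = markov_lifetime_qalys(
            70, "male", life_table, constant_norms, EconParams(half_cycle_correction=True)
        )
        assert hcc > plain  # start-of-cycle occupancy adds half a cycle

    def test_missing_life_table_age_is_an_error(self, constant_norms, econ):
        lt = make_life_table({a: 0.01 for a in range(70, 80)})
        with pytest.raises(ValueError, match="life table"):
            markov_lifetime_qalys(85, "male", lt, constant_norms, econ)


def outcomes_frame(rows):
    return pd.DataFrame(rows)


class TestTransitionProbabilities:
    def test_all_hospital_deaths(self):
        df = outcomes_frame(
            [
                {"arm": "baseline_pct", "weight": 1.0, "died_in_hospital": True, "alive_at_1y": False}
                for _ in range(4)
            ]
        )
        t = estimate_transition_probabilities(df)
        row = t.set_index("arm").loc["baseline_pct"]
        assert row["p_hospitalized_dead"] == 1.0
        assert math.isnan(row["p_discharged_markov"])

    def test_branch_probabilities_sum_to_one(self, default_cohort_outcomes):
        t = estimate_transition_probabilities(default_cohort_outcomes)
        assert set(t["arm"]) == {"baseline_pct", "no_baseline_pct"}
        for _, row in t.iterrows():
            assert row["p_hospitalized_dead"] + row["p_hospitalized_discharged"] == pytest.approx(1)
            assert row["p_discharged_dead"] + row["p_discharged_markov"] == pytest.approx(1)

    def test_duplicated_records_equal_doubled_weights(self):
        base = [
            {"arm": "a", "weight": 1.0, "died_in_hospital": True, "alive_at_1y": False},
            {"arm": "a", "weight": 1.0, "died_in_hospital": False, "alive_at_1y": True},
            {"arm": "a", "weight": 1.0, "died_in_hospital": False, "alive_at_1y": False},
        ]
        doubled = outcomes_frame(base + base)
        reweighted = outcomes_frame(
            [{**r, "weight": 2.0} for r in base]
        )
        ta = estimate_transition_probabilities(doubled).drop(columns="arm")
        tb = estimate_transition_probabilities(reweighted).drop(columns="arm")
        assert np.allclose(ta.to_numpy(dtype=float), tb.to_numpy(dtype=float))

    def test_empty_arm_is_an_error(self):
        df = outcomes_frame([{"arm": "a", "weight": 0.0, "died_in_hospital": False, "alive_at_1y": True}])
        with pytest.raises(ValueError, match="zero total weight"):
            estimate_transition_probabilities(df)


class TestCohortCalibration:
    def test_weighted_baseline_utility_near_published_value(self, default_cohort_outcomes):
        """Default cohort (age ~70, 56% male) against the bundled norms gives
        a weighted mean baseline utility near 0.767."""
        df = default_cohort_outcomes
        u = np.average(df["baseline_utility"], weights=df["weight"])
        assert u == pytest.approx(0.767, abs=0.02)

    def test_markov_qalys_zero_unless_alive_at_one_year(self, default_cohort_outcomes):
        df = default_cohort_outcomes
        dead = df[~df["alive_at_1y"]]
        assert (dead["qalys_markov"] == 0).all()
        alive = df[df["alive_at_1y"]]
        assert (alive["qalys_markov"] > 0).all()
        assert np.allclose(df["qalys_total"], df["qalys_dt"] + df["qalys_markov"])
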