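import numpy as np
import pandas as pd
import pytest

from peach_cea.abx_costing import load_default_price_table, load_default_rules
from peach_cea.econ_model import (
    EconParams,
    LifeTable,
    UtilityNorms,
    load_default_life_table,
    load_default_utility_norms,
)


@pytest.fixture(scope="session")
def rules():
    return load_default_rules()


@pytest.fixture(scope="session")
def price_table():
    return load_default_price_table()


@pytest.fixture(scope="session")
def norms():
    return load_default_utility_norms()


@pytest.fixture(scope="session")
def life_table():
    return load_default_life_table()


@pytest.fixture(scope="session")
def econ():
    return EconParams()


@pytest.fixture(scope="session")
def constant_norms():
    """Flat utility norms u=0.8 for all ages and both sexes."""
    frame = pd.DataFrame(
        {
            "age_low": [16, 16],
            "age_high": [110, 110],
            "sex": ["male", "female"],
            "utility": [0.8, 0.8],
        }
    )
    return UtilityNorms(frame)


def make_life_table(q_by_age: dict, sexes=("male", "female")) -> LifeTable:
    rows = [
        {"age": age, "sex": sex, "qx": q} for age, q in q_by_age.items() for sex in sexes
    ]
    return LifeTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_cohort_outcomes():
    """Default-calibrated synthetic cohort (n=5000, seed=1) run through QC,
    costing and the economic model; shared across tests for speed."""
    from peach_cea.abx_costing import cost_antibiotics
    from peach_cea.cohort_qc import apply_exclusions
    from peach_cea.econ_model import compute_outcomes
    from peach_cea.synthetic_cohort import CohortGenParams, generate_cohort

    cohort = generate_cohort(CohortGenParams(n_patients=5000, seed=1))
    clean, _ = apply_exclusions(cohort)
    rules = load_default_rules()
    table = load_default_price_table()
    costed = [cost_antibiotics(p.antibiotic_records, rules, table) for p in clean]
    return compute_outcomes(
        clean, costed, EconParams(), load_default_utility_norms(), load_default_life_table()
    )


def weighted_se(values, weights) -> float:
    """Standard error of a weighted mean (linearization estimate)."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    m = np.average(x, weights=w)
    wn = w / w.sum()
    return float(np.sqrt(np.sum(wn**2 * (x - m) ** 2)))
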