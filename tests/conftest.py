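import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fedstats.cohort import CohortTable, StudyConfig
from fedstats.federation import Node
from fedstats.synthetic import build_fixture, table1_spec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig()


@pytest.fixture(scope="session")
def fixture_tables():
    """The deterministic published-marginals cohort (3 centers)."""
    return build_fixture(table1_spec(), seed=0)


@pytest.fixture(scope="session")
def fixture_pooled(fixture_tables):
    return pd.concat([t.df for t in fixture_tables], ignore_index=True)


def make_table(
    center="c1",
    n=10,
    period="before",
    creatinemia=None,
    duration=None,
    secondline=None,
    transfer=None,
    gender=None,
    seed=0,
    config=None,
):
    """Small hand-rolled cohort table for unit tests."""
    rng = np.random.default_rng(seed)
    base = dt.date(2019, 6, 1) if period == "before" else dt.date(2020, 6, 1)
    df = pd.DataFrame(
        {
            "patient_id": [f"{center}-{i}" for i in range(n)],
            "center": center,
            "inclusion_date": [base + dt.timedelta(days=int(d)) for d in rng.integers(0, 120, n)],
            "gender": gender if gender is not None else rng.choice(["Female", "Male"], n),
            "age_class": rng.choice(["<55", "55-65", ">65"], n),
            "bmi_class": rng.choice(["<18.5", "18.5-25", ">25"], n),
            "treatment_category": rng.choice(["Chemotherapy", "Immunotherapy"], n),
            "creatinemia": creatinemia if creatinemia is not None else rng.normal(65, 15, n),
            "firstline_duration_days": duration
            if duration is not None
            else rng.lognormal(4.5, 1.0, n),
            "secondline_start_day": secondline if secondline is not None else np.nan,
            "death_day": np.nan,
            "transfer_day": transfer if transfer is not None else np.nan,
        }
    )
    return CohortTable(df, config=config)


@pytest.fixture
def make_cohort_table():
    return make_table


@pytest.fixture
def fixture_nodes(fixture_tables):
    return [Node(t.center, t) for t in fixture_tables]
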