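import numpy as np
import pandas as pd
import pytest

from sleepcourse.pipeline import FilterConfig, apply_inclusion_filters
from sleepcourse.synthetic import CohortConfig, GroundTruth, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A filtered mid-size cohort with its ground truth (session-cached)."""
    records, truth = generate_cohort(CohortConfig(n_participants=8_000, seed=7))
    kept, _ = apply_inclusion_filters(records, FilterConfig(min_country_n=1))
    return kept, truth


@pytest.fixture(scope="session")
def large_cohort():
    """n=200k default-config cohort, seed 1 (shared across heavier tests)."""
    records, truth = generate_cohort(CohortConfig(n_participants=200_000, seed=1))
    return records, truth


def make_truth(pids, nav, motor):
    """Hand-built GroundTruth for trajectory tests with chosen latent skills."""
    return GroundTruth(
        true_changepoints=(33.0, 53.0),
        gender_offset=0.13,
        country_table=pd.DataFrame({
            "country": ["K01"], "intercept": [0.0], "effective_intercept": [0.0],
            "cluster": ["G1"], "weird": [True],
            "abs_latitude": [45.0], "gdp_per_capita": [3e4],
        }),
        skill_link={"young": (0.0, 0.0), "middle": (0.0, 0.0), "older": (0.0, 0.0)},
        nav_skill=pd.Series(np.asarray(nav, dtype=float), index=pids),
        motor_skill=pd.Series(np.asarray(motor, dtype=float), index=pids),
    )


def make_records(pids, age=30):
    return pd.DataFrame({
        "participant_id": list(pids),
        "age": age,
        "gender": "man",
        "education": "tertiary",
        "home_env": "city",
        "commute": "<30min",
        "country": "K01",
        "sleep_hours": 7,
    })
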