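import warnings

import numpy as np
import pandas as pd
import pytest

import beliefupdate as bu


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject study generated from RL model 1 with default conditions."""
    cfg = bu.CohortConfig(
        group_sizes={"oct2019": 3, "mar2020": 3, "may2021": 3, "jun2022": 3},
        two_run_counts={"oct2019": 3, "mar2020": 0, "may2021": 0, "jun2022": 2},
        seed=42)
    trials, params = bu.generate_study(cfg)
    return cfg, trials, params


@pytest.fixture(scope="session")
def small_retained(small_cohort):
    _, trials, _ = small_cohort
    retained, _ = bu.apply_exclusions(bu.add_measures(trials))
    return retained


@pytest.fixture(scope="session")
def measured_cohort_123():
    """Default-size (123-subject) study with per-subject parameter spread."""
    cfg = bu.CohortConfig(seed=7)
    trials, params = bu.generate_study(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained, counts = bu.apply_exclusions(bu.add_measures(trials))
    return cfg, trials, params, retained, counts


def make_trials(br, e1, ebr, e2=None, responded=None, subject_id=1):
    """Hand-built trial table with the generator's schema."""
    br = np.atleast_1d(br).astype(float)
    n = br.size
    frame = pd.DataFrame({
        "subject_id": subject_id, "group": "oct2019", "context": 0,
        "design": 1, "age": 30.0, "gender": 1, "education": 5.0,
        "event_id": np.arange(1, n + 1), "base_rate": br,
        "e1": np.atleast_1d(e1).astype(float),
        "ebr": np.atleast_1d(ebr).astype(float),
        "confidence": 50.0,
        "e2": np.full(n, np.nan) if e2 is None else np.atleast_1d(e2).astype(float),
        "responded": np.ones(n, dtype=int) if responded is None
        else np.atleast_1d(responded).astype(int),
    })
    return frame
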