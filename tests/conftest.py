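import numpy as np
import pytest

from hfreadmit.simulate import SimConfig, simulate_cohort
from hfreadmit.timelines import ClaimEvent, build_timelines


def make_event(pid="P0", admit=0, discharge=5, primary="108", age=70,
               sex="F", pay="Medicare", secondary=(), procedures=(),
               comorbidities=()):
    return ClaimEvent(patient_id=pid, admit_day=admit,
                      discharge_day=discharge, primary_dx=primary,
                      secondary_dx=tuple(secondary),
                      procedures=tuple(procedures),
                      comorbidities=tuple(comorbidities),
                      age_years=age, sex=sex, pay_source=pay)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest history-free synthetic cohort shared across tests."""
    cfg = SimConfig(n_patients=800, seed=11)
    claims, truth = simulate_cohort(cfg)
    timelines = build_timelines(claims)
    return cfg, claims, truth, timelines


@pytest.fixture(scope="session")
def history_cohort():
    """A cohort whose readmission mechanism depends on history."""
    cfg = SimConfig(n_patients=1500, beta_history=2.0, seed=23)
    claims, truth = simulate_cohort(cfg)
    timelines = build_timelines(claims)
    return cfg, claims, truth, timelines


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
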