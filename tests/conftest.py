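from datetime import date

import pytest
from hypothesis import settings

from chronodst.config import CohortConfig, RunConfig

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from chronodst.synthetic import generate_cohort

DST_2019 = date(2019, 3, 10)


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort under default study-like conditions (shared across
    tests; treat as read-only)."""
    return generate_cohort(CohortConfig(n_subjects=250, seed=11))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """All night-level noise and dropout off: downstream estimates must
    recover the configured dynamics exactly."""
    cfg = CohortConfig(n_subjects=45, seed=7, onset_jitter_sd=0.0,
                       duration_sd=0.0, short_event_rate=0.0,
                       missing_night_rate=0.0)
    return generate_cohort(cfg)


@pytest.fixture()
def run_config():
    return RunConfig(dst_date=DST_2019)
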