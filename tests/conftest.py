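import numpy as np
import pandas as pd
import pytest

from behaviorome import synthetic as syn

pytest_plugins = ()


@pytest.fixture(scope="session")
def tiny_config() -> syn.CohortConfig:
    return syn.CohortConfig(n_participants=3, n_days=7, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return syn.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def profile() -> syn.RoutineProfile:
    return syn.default_profile("P000", np.random.default_rng(7))


@pytest.fixture(scope="session")
def one_day(profile):
    """(ambient events, watch frame) for one simulated day."""
    rng = np.random.default_rng(3)
    date = pd.Timestamp("2024-03-06")
    schedule = syn.resolve_schedule(profile, date, rng)
    ambient = syn.simulate_ambient_day(profile, date, rng, schedule)
    watch = syn.simulate_watch_day(profile, date, rng, schedule)
    return ambient, watch
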