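import numpy as np
import pytest

from methylpanel.qmsp import build_profiles
from methylpanel.simulate import default_config_table1, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-composition synthetic cohort (108 cases / 100 controls)."""
    config = default_config_table1(seed=20240)
    records, clinical = simulate_cohort(config)
    return config, records, clinical


@pytest.fixture(scope="session")
def default_profiles(default_cohort):
    _, records, clinical = default_cohort
    return build_profiles(records), clinical


@pytest.fixture(scope="session")
def clean_cohort():
    """Default cohort without ACTB failures: every multiplex valid."""
    config = default_config_table1(seed=31, actb_failure_rate=0.0)
    records, clinical = simulate_cohort(config)
    return build_profiles(records), clinical


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
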