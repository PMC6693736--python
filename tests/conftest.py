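import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cohowtp as cw

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design():
    """4-version design over the default restricted grid."""
    return cw.generate_design(cw.DesignConfig(n_versions=4, seed=101))


@pytest.fixture(scope="session")
def homogeneous_dataset(small_design):
    """Choices from a taste-homogeneous population (conditional logit truth)."""
    params = cw.RPLParams().with_zero_sds()
    cfg = cw.PopulationConfig(
        n_respondents=600, params=params, seed=7, task_nonresponse_rate=0.0
    )
    _, data = cw.simulate_dataset(cfg, small_design)
    return data


@pytest.fixture(scope="session")
def heterogeneous_dataset(small_design):
    """Choices from the default heterogeneous population (small n)."""
    cfg = cw.PopulationConfig(n_respondents=150, seed=11)
    _, data = cw.simulate_dataset(cfg, small_design)
    return data
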