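import numpy as np
import pytest
from hypothesis import settings

from padtrack.config import ModelOptions, RunConfig, SimulationConfig, VolumeParams
from padtrack.pipeline import run_analysis
from padtrack.simulate import simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: Small cohort + small grid used for shared end-to-end fixtures; the
#: statistical structure (three groups, attrition, family nesting) is the
#: default one, only the sizes shrink.
SMALL_SIM = SimulationConfig(
    group_sizes=(14, 12, 8),
    followup_counts=(8, 8, 6),
    volume_params=VolumeParams(shape=(20, 24, 20)),
    seed=3,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def small_run():
    """One full analysis on a small synthetic cohort, shared across tests."""
    cfg = RunConfig(simulation=SMALL_SIM, model=ModelOptions(), seed=3)
    return run_analysis(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
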