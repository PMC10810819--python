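import pytest

from mirstab.config import SimulationConfig
from mirstab.pipeline import run_pipeline
from mirstab.simulate import simulate_study

from _driver import reduced_config, run_stages, tiny_config


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default (study-scale) synthetic study."""
    return run_pipeline(sim_config=SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def default_truth():
    study, truth = simulate_study(SimulationConfig(), seed=1)
    return study, truth


@pytest.fixture(scope="session")
def tiny_study():
    return simulate_study(tiny_config(), seed=2)


@pytest.fixture(scope="session")
def reduced_stages():
    """Stage-wise outputs for one reduced-panel study-scale simulation."""
    study, truth = simulate_study(reduced_config(), seed=11)
    return study, truth, run_stages(study)
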