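import pytest

from beeforage.event_model import TreatmentName
from beeforage.physiology import DEFAULT_PARAMS
from beeforage.synthetic_data import (
    SimulationConfig,
    simulate_experiment,
    simulate_treatment_group,
)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def small_dataset():
    """Three low-difference bees, full two-phase logs."""
    return simulate_treatment_group(
        SimulationConfig(rng_seed=7), TreatmentName.LOW_DIFFERENCE, n_bees=3
    )


@pytest.fixture(scope="session")
def full_dataset():
    """The complete 36-bee synthetic experiment."""
    return simulate_experiment(SimulationConfig(rng_seed=11))
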