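import numpy as np
import pytest

from methmix import MCMCConfig, PanelSimSpec, simulate_panel
from methmix.types import HMMHyper, HMMParameterState


@pytest.fixture(scope="session")
def small_panel():
    """Three-state two-group panel with missingness, used across modules."""
    spec = PanelSimSpec(n_positions=300, n_samples_per_group=4,
                        missing_rate=0.25, dmc_fraction=0.1, seed=11)
    return simulate_panel(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def two_state_params():
    trans = np.array([[0.5, 0.5],
                      [0.8, 0.2],
                      [0.3, 0.7]])
    return HMMParameterState(2, np.array([0.2, 0.7]), trans, HMMHyper())


@pytest.fixture()
def light_chain():
    return MCMCConfig(n_iter=300, burn_in=120, thin=2, seed=5)
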