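import numpy as np
import pandas as pd
import pytest

from oddballiem.design import SequenceConfig, label_conditions, simulate_design
from oddballiem.simulate import SimulationParams, make_ground_truth, simulate_epochs


@pytest.fixture(scope="session")
def small_config():
    """Shrunken design for fast tests: full-size blocks, but fewer of them."""
    return SequenceConfig(n_roving_blocks=2, n_equiprobable_blocks=1)


@pytest.fixture(scope="session")
def small_events(small_config):
    return simulate_design(small_config, "attended", seed=11)


@pytest.fixture(scope="session")
def small_epochs(small_config, small_events):
    params = SimulationParams(n_electrodes=12, n_noise_sources=6)
    truth = make_ground_truth(params, rng=np.random.default_rng(5))
    return simulate_epochs(small_events, truth, params, rng=np.random.default_rng(6))


@pytest.fixture(scope="session")
def grid_events():
    """Hand-built event table covering every orientation on the 20-deg grid."""
    orients = np.tile(np.arange(9) * 20.0, 4)
    n = orients.size
    ev = pd.DataFrame(
        {
            "block": np.repeat(np.arange(4), 9),
            "onset_s": np.tile(np.arange(9) * 0.6, 4),
            "orientation_deg": orients,
            "sequence_type": "equiprobable",
            "train_position": 1,
            "train_length": 1,
            "is_target": False,
        }
    )
    return label_conditions(ev, "attended")
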