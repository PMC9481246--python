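import numpy as np
import pandas as pd
import pytest

from driftlab.session import Session
from driftlab.synth import SynthConfig, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One default independent-regime synthetic session with ground truth."""
    return simulate_session(SynthConfig(), seed=0)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_units=20, repeats_per_block=4, gap_bins=40,
                       edge_bins=10)


@pytest.fixture(scope="session")
def small_session(small_config):
    return simulate_session(small_config, seed=0)


@pytest.fixture()
def tiny_session():
    """Hand-built 3-unit, 10-bin session covering every component."""
    units = pd.DataFrame(
        {"unit_id": ["a", "b", "c"], "region": ["V1", "V1", "CA1"]}
    )
    counts = np.arange(30, dtype=float).reshape(3, 10)
    counts[1, 4] = np.nan
    behavior = pd.DataFrame(
        {
            "pupil_width": np.linspace(1, 2, 10),
            "pupil_x": np.zeros(10),
            "pupil_y": np.zeros(10),
            "running_speed": np.linspace(0, 5, 10),
        }
    )
    behavior.loc[3, "pupil_width"] = np.nan
    epochs = pd.DataFrame(
        {
            "stimulus_name": ["movie"] * 8,
            "block": [0, 0, 0, 0, 1, 1, 1, 1],
            "repeat": [0, 0, 1, 1, 0, 0, 1, 1],
            "frame": [0, 1, 0, 1, 0, 1, 0, 1],
            "bin": [0, 1, 2, 3, 5, 6, 7, 8],
        }
    )
    return Session(units=units, counts=counts, behavior=behavior,
                   epochs=epochs, meta={"origin": "test"}).validate()
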