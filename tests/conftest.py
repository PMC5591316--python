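import numpy as np
import pytest

import ribofret as rf


@pytest.fixture
def noiseless_photo():
    """Ideal detector: no noise, no background, identity leakage, equal
    detection for all dyes."""
    return rf.PhotophysicsParams(
        noise_model="none",
        background=np.zeros(3),
        leakage=np.eye(3),
        gamma=(1.0, 1.0, 1.0),
    )


@pytest.fixture
def single_state_scheme():
    """Static complex pinned in the docked state with known efficiencies."""
    return rf.KineticScheme(
        state_efficiencies={"docked": (0.5, 0.2, 0.3), "flipped": (0.5, 0.2, 0.3)},
        rates_pre={"dock_to_flip": 0.0, "flip_to_dock": 0.0},
    )


@pytest.fixture
def two_state_scheme():
    return rf.KineticScheme(
        state_efficiencies={"docked": (0.61, 0.25, 0.15), "flipped": (0.33, 0.25, 0.1)},
        rates_pre={"dock_to_flip": 1.0, "flip_to_dock": 3.0},
    )
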