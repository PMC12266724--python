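import numpy as np
import pytest

from clapipe.config import SimConfig
from clapipe.imaging import StimulusSchedule


@pytest.fixture
def small_config():
    return SimConfig(seed=11, n_units=8, n_trials=24)


@pytest.fixture
def simple_schedule():
    """Three trials of known types, far from the recording edges."""
    return StimulusSchedule(
        np.array(["whisker", "sound", "sound+light"], dtype=object),
        np.array([5.0, 15.0, 25.0]),
        0.5,
    )
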