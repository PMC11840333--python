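import numpy as np
import pytest

from synlink.cohort import default_aif
from synlink.kinetics import FrameSchedule


@pytest.fixture(scope="session")
def aif():
    return default_aif()


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240610)
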