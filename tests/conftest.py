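import numpy as np
import pytest
from hypothesis import settings

from sourcemem.task_data import FrequencyTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def exact_table():
    """Counts lying exactly on the category probabilities of
    (S_up=0.5, S_down=0.5, I_up=0.4, I_down=0.4, o=0.2, g=0.6), N=1000/tree."""
    return FrequencyTable([[656, 104, 240],
                           [156, 604, 240],
                           [120,  80, 800]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
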