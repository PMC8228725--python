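import numpy as np
import pytest

from aphidmir import preset_config
from aphidmir.synthetic_data import generate_all


@pytest.fixture(scope="session")
def small_bundle():
    """One small synthetic study shared by read-level and pipeline tests."""
    return generate_all(preset_config("small", seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
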