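import numpy as np
import pytest
from hypothesis import settings

from matcare.config import SimConfig

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A light configuration for fast generator tests."""
    return SimConfig(seed=7, n_units_per_class=3, usv_n_per_category=10,
                     n_animals=3, cells_per_image=50, cells_per_group=60)
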