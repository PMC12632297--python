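import numpy as np
import pytest

from boldwaves import SimConfig, make_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def geometry280():
    """280 vertices / 70 bins: divisible, so every bin holds 4 vertices."""
    return make_geometry(280, 70, 14, seed=3)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A desk-scale cohort for pipeline-level tests."""
    return SimConfig(n_retained=6, n_excluded_low=2, n_excluded_high=1,
                     n_vertices=280, n_runs=2, master_seed=11)
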