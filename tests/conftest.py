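import numpy as np
import pytest

from bassgeo.environment import make_environment
from bassgeo.simulate import record_tag, simulate_track

SWITCH = np.array([[0.9, 0.1], [0.1, 0.9]])


@pytest.fixture(scope="session")
def flat_env():
    """Small all-sea grid with constant 40 m depth."""
    return make_environment(12, 12, n_days=40, seed=2, bathymetry="flat")


@pytest.fixture(scope="session")
def coastal_env():
    return make_environment(20, 20, n_days=60, seed=7, bathymetry="coastal_gradient")


@pytest.fixture(scope="session")
def tiny_env():
    """3x3 grid for exhaustive-enumeration oracles."""
    return make_environment(3, 3, n_days=6, seed=2, bathymetry="flat")


@pytest.fixture(scope="session")
def small_track(flat_env):
    return simulate_track(flat_env, 3.0, 30.0, SWITCH, 12, (6, 6), seed=5)


@pytest.fixture(scope="session")
def small_archive(flat_env, small_track):
    return record_tag(small_track, flat_env, seed=5)
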