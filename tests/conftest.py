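import numpy as np
import pytest

from apopsynergy.models import build_variant
from apopsynergy.network import default_grid, integrate
from apopsynergy.population import PopulationSpec
from apopsynergy.ros_cflip import build_ros_cflip_network


@pytest.fixture(scope="session")
def trail_variant():
    return build_variant("trail_only")


@pytest.fixture(scope="session")
def ly30_variant():
    return build_variant("ly30_only")


@pytest.fixture(scope="session")
def combo_variant():
    return build_variant("combination")


@pytest.fixture(scope="session")
def combo_trajectory(combo_variant):
    """Deterministic mean-cell combination run, 0-24 h."""
    return integrate(combo_variant.network, combo_variant.events,
                     default_grid(24.0))


@pytest.fixture(scope="session")
def ros_network():
    return build_ros_cflip_network()


@pytest.fixture
def small_spec():
    """Small but non-trivial Monte Carlo spec for fast tests."""
    return PopulationSpec(n_cells=30, cv=0.4, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
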