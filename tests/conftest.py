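import numpy as np
import pytest

from podofp.geometry import build_idealized_podocyte, to_network
from podofp.presets import get_params
from podofp.spatial import SpatialParams


@pytest.fixture(scope="session")
def geom():
    return build_idealized_podocyte(seed=0)


@pytest.fixture(scope="session")
def network(geom):
    return to_network(geom)


@pytest.fixture(scope="session")
def baseline():
    return get_params("fig2C")


@pytest.fixture(scope="session")
def spatial_params(baseline):
    return SpatialParams(kinetics=baseline)


@pytest.fixture(scope="session")
def fig3_result(network, spatial_params):
    """Global bundling-increase scenario, shared by several tests."""
    from podofp.spatial import run_scenario

    return run_scenario("fig3_global_ab", network, spatial_params)
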