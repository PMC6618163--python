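import numpy as np
import pytest

from cardiouq.fibers import AngleBC, assign_fiber_frame, solve_transmural_coordinate
from cardiouq.geometry import LVGeometryConfig, build_idealized_lv


@pytest.fixture(scope="session")
def default_config():
    return LVGeometryConfig()


@pytest.fixture(scope="session")
def default_mesh(default_config):
    """The calibrated study mesh (no FE solves in tests that only need it)."""
    return build_idealized_lv(default_config)


@pytest.fixture(scope="session")
def coarse_config():
    """Coarser variant used by tests that run nonlinear solves."""
    return LVGeometryConfig(target_edge_length=1.8)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_config):
    return build_idealized_lv(coarse_config)


@pytest.fixture(scope="session")
def coarse_transmural(coarse_mesh):
    return solve_transmural_coordinate(coarse_mesh)


@pytest.fixture(scope="session")
def coarse_frame(coarse_mesh, coarse_transmural):
    return assign_fiber_frame(coarse_mesh, coarse_transmural, AngleBC())


@pytest.fixture(scope="session")
def sphere_config():
    """Hemispherical shell: concentric spheres cut through their center."""
    return LVGeometryConfig(
        endo_semi_axes=(2.0, 2.0, 2.0),
        epi_semi_axes=(3.0, 3.0, 3.0),
        base_cut_height=3.0,
        target_edge_length=0.3,
    )


@pytest.fixture(scope="session")
def sphere_mesh(sphere_config):
    return build_idealized_lv(sphere_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
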