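import numpy as np
import pytest

from cceit.geometry import Grid
from cceit.phantom import assign_region_properties, build_healthy_phantom
from cceit.sampler import load_tables, sample_geometry
from cceit.solver import SensorModel, field_from_phantom


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def geometry(tables):
    return sample_geometry(tables, rng_seed=11)


@pytest.fixture(scope="session")
def properties():
    return assign_region_properties(rng_seed=11)


@pytest.fixture(scope="session")
def sensor():
    return SensorModel()


@pytest.fixture(scope="session")
def image_grid(tables):
    return Grid(tables.image_extent, 64)


@pytest.fixture(scope="session")
def phantom(geometry, properties, image_grid):
    return build_healthy_phantom(geometry, properties, image_grid)


@pytest.fixture(scope="session")
def solver_phantom(geometry, properties, sensor):
    return build_healthy_phantom(geometry, properties, sensor.default_grid(64))


@pytest.fixture(scope="session")
def solver_field(solver_phantom, sensor):
    return field_from_phantom(solver_phantom, sensor)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
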