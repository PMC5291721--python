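import numpy as np
import pytest

from fasim import (
    ElasticMaterial,
    build_disc_mesh,
    build_square_mesh,
    build_triangle_mesh,
)


@pytest.fixture(scope="session")
def disc_mesh():
    return build_disc_mesh(10.0, 1.0)


@pytest.fixture(scope="session")
def coarse_disc():
    return build_disc_mesh(10.0, 2.0)


@pytest.fixture(scope="session")
def tri_mesh():
    return build_triangle_mesh(30.0, 1.5)


@pytest.fixture(scope="session")
def square_mesh():
    return build_square_mesh(40.0, 4.0)


@pytest.fixture(scope="session")
def soft_material():
    return ElasticMaterial(0.5, 0.3)


@pytest.fixture(scope="session")
def gel_material():
    return ElasticMaterial(1.0, 0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
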