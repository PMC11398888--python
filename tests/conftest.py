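import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fosda import TriangleMesh, assemble_penalty, make_template

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sphere1():
    """42-vertex unit icosphere."""
    return make_template(1)


@pytest.fixture(scope="session")
def sphere2():
    """162-vertex unit icosphere."""
    return make_template(2)


@pytest.fixture(scope="session")
def sphere3():
    """642-vertex unit icosphere."""
    return make_template(3)


@pytest.fixture(scope="session")
def ops1(sphere1):
    return assemble_penalty(sphere1, epsilon=1e-3)


@pytest.fixture(scope="session")
def ops2(sphere2):
    return assemble_penalty(sphere2, epsilon=1e-3)


@pytest.fixture()
def single_triangle():
    return TriangleMesh(vertices=np.array([[0.0, 0.0, 0.0],
                                           [1.0, 0.0, 0.0],
                                           [0.0, 1.0, 0.0]]),
                        faces=np.array([[0, 1, 2]]))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
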