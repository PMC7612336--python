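import numpy as np
import pytest

from sulcalstrain import geometry, kinematics, solver


@pytest.fixture(scope="session")
def coarse_mesh():
    """Small sulcated mesh for fast solver tests (6 mm elements)."""
    return geometry.build_sulcal_mesh(element_size=6e-3)


@pytest.fixture(scope="session")
def default_specs():
    return kinematics.default_profile_specs()


@pytest.fixture(scope="session")
def materials():
    return solver.default_materials()


@pytest.fixture()
def unit_quad():
    """Reference unit-square element."""
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
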