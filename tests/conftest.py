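import numpy as np
import pytest

from gradsafe.coils import make_axis_coil, make_ideal_field
from gradsafe.em_solver import SolveConfig, solve_E
from gradsafe.phantoms import BodyParams, make_homogeneous_cylinder, make_torso_phantom
from gradsafe.sweep import dAdt_on_grid


@pytest.fixture(scope="session")
def uniform_b_100():
    """Uniform axial B switched at 100 T/s."""
    return make_ideal_field("uniform_B", 1.0, rate=100.0)


@pytest.fixture(scope="session")
def torso_3mm():
    return make_torso_phantom(BodyParams(resolution=3.0))


@pytest.fixture(scope="session")
def torso_3mm_efield(torso_3mm, uniform_b_100):
    dAdt = dAdt_on_grid(uniform_b_100, torso_3mm, slew=100.0)
    return solve_E(torso_3mm, dAdt, SolveConfig(rel_tolerance=1e-8))


@pytest.fixture(scope="session")
def circle_2mm():
    """Homogeneous circular cylinder r=0.2 m, thin slab, 2 mm voxels."""
    return make_homogeneous_cylinder(0.2, 0.2, 0.02, sigma=0.23, resolution=2.0)


@pytest.fixture(scope="session")
def circle_2mm_efield(circle_2mm, uniform_b_100):
    dAdt = dAdt_on_grid(uniform_b_100, circle_2mm, slew=100.0)
    return solve_E(circle_2mm, dAdt)


@pytest.fixture(scope="session")
def maxwell_z():
    return make_axis_coil("Z", inner_diameter=0.70, length=1.40)


@pytest.fixture(scope="session")
def golay_x():
    return make_axis_coil("X", inner_diameter=0.70, length=1.40)
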