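import numpy as np
import pytest

from lgmf import units
from lgmf.engine import LGMFConfig
from lgmf.surfaces import (
    QuadraticSurface,
    TwoStatePES,
    make_model_2d_pair,
    make_quadratic_pair,
)


@pytest.fixture
def pair_1d():
    """The scalar reference pair: H0=1, H1=2, g1=1, gap 10 at the origin."""
    s0 = QuadraticSurface([0.0], 0.0, [0.0], [[1.0]])
    s1 = QuadraticSurface([0.0], 10.0, [1.0], [[2.0]])
    return TwoStatePES(s0, s1)


@pytest.fixture
def diag_2d_pair():
    """Block-diagonal pair: H0=I, H1=diag(2,3), g1=(1,0)."""
    s0 = QuadraticSurface([0.0, 0.0], 0.0, [0.0, 0.0], np.eye(2))
    s1 = QuadraticSurface([0.0, 0.0], 5.0, [1.0, 0.0],
                          np.diag([2.0, 3.0]))
    return TwoStatePES(s0, s1)


@pytest.fixture(scope="session")
def model2d():
    return make_model_2d_pair()


@pytest.fixture
def quad_pair_6d():
    return make_quadratic_pair(6, seed=3)


def nn(x: float) -> float:
    """Force in nN → Hartree/Bohr."""
    return units.convert(x, "nN", "hartree/bohr")


@pytest.fixture
def tight_config():
    """High-accuracy ramp configuration for closed-form comparisons."""
    return LGMFConfig(force_max=nn(0.5), cos_tolerance=1 - 1e-10)
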