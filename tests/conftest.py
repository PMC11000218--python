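import numpy as np
import pytest

from unbindkit.potentials import DoubleWell1D, RadialBinding2D


@pytest.fixture(scope="session")
def double_well():
    return DoubleWell1D(barrier=5.0, x0=1.0)


@pytest.fixture(scope="session")
def radial_potential():
    return RadialBinding2D()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
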