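import numpy as np
import pytest

from modbalance.gpfm import FitnessParams, GPFMSpec, solve_initial_traits


@pytest.fixture(scope="session")
def a_default() -> FitnessParams:
    """The standard selection scales: trait 2 under 2x stronger selection."""
    return FitnessParams(a1=1.0, a2=0.5)


@pytest.fixture(scope="session")
def contour_start(a_default):
    """Canonical initial condition on the F0 = -1.39 contour with R0 = 1.25."""
    return solve_initial_traits(-1.39, 1.25, a_default)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def modular_spec():
    return GPFMSpec("modular", delta=0.1, L1=200, L2=200)
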