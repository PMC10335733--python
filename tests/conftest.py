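import numpy as np
import pytest

from t6sim.kinetics import KineticParams
from t6sim.mechanics import Arena, StrainSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20230613)


@pytest.fixture
def es401_fit_params():
    """The fitted activation triple of the faster-activating strain."""
    return KineticParams(p0=0.10, tau_plus=1.34, lambda_plus=0.118)


@pytest.fixture
def wt_kinetics():
    """Wildtype-style full kinetic parameter set (sheath mean 3.5)."""
    return KineticParams(p0=0.10, tau_plus=1.0, lambda_plus=0.6, lambda_s=21.0, lambda_f=6.0)


@pytest.fixture
def small_arena():
    return Arena(Lx=40.0, Ly=40.0, boundary="periodic")


@pytest.fixture
def open_arena():
    return Arena(Lx=60.0, Ly=60.0, boundary="open")


@pytest.fixture
def basic_strain(wt_kinetics):
    return StrainSpec(name="wt", kinetics=wt_kinetics)
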