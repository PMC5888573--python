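import numpy as np
import pytest

from mazsim import GrowthCoupling, KineticParams, StressProtocol
from mazsim.reactions import SpeciesState


@pytest.fixture
def params():
    return KineticParams()


@pytest.fixture
def coupling():
    return GrowthCoupling()


@pytest.fixture
def no_stress():
    """A stress window far outside any simulated horizon."""
    return StressProtocol(t_on=1e8, t_off=2e8)


@pytest.fixture
def linear_params():
    """Transcription/translation/decay only: no binding, no operator, no
    cleavage -- the analytically solvable sub-network."""
    return KineticParams(
        k_tx=2.0, b_A=1.0, b_T=0.3, delta_A=0.1, delta_T=0.02, delta_m=0.2,
        k_cleave=0.0, kon=0.0, koff=0.0, kb_A=0.0, kb_C=0.0, kb_T2=0.0,
        beta_ect=0.0,
    )


@pytest.fixture
def empty_state():
    return SpeciesState()


def linear_ode_means(p: KineticParams, t: float):
    """Closed-form means of the linear sub-network started from zero.

    dm/dt = k_tx - delta_m m ; dA/dt = b_A m - delta_A A ;
    dT/dt = b_T m - delta_T T.
    """
    m_inf = p.k_tx / p.delta_m
    m = m_inf * (1 - np.exp(-p.delta_m * t))

    def protein(b, d):
        x_inf = b * m_inf / d
        # solution of dx/dt = b m(t) - d x with x(0)=0
        return x_inf * (1 - np.exp(-d * t)) - b * m_inf / (d - p.delta_m) * (
            np.exp(-p.delta_m * t) - np.exp(-d * t))

    return m, protein(p.b_A, p.delta_A), protein(p.b_T, p.delta_T)
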