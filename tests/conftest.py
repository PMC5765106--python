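import numpy as np
import pytest

from starwta import (CouplingParams, FullState, ModelParams, ReducedState,
                     integrate)


@pytest.fixture(scope="session")
def coupling_default():
    return CouplingParams(nu=20.0, mu=1.0, sigma=100.0)


@pytest.fixture(scope="session")
def params_n3(coupling_default):
    """Three-PO model with one stationary winner (all detunings < |b|)."""
    return ModelParams(omega=np.array([5.0, 5.5, 4.2]), b=-1.0, alpha=1.0,
                       beta=0.05, gamma=10.0, c=2.0, coupling=coupling_default)


@pytest.fixture(scope="session")
def params_n3_identical(coupling_default):
    return ModelParams(omega=np.full(3, 5.0), b=-1.0, alpha=1.0, beta=0.05,
                       gamma=10.0, c=2.0, coupling=coupling_default)


@pytest.fixture
def state_advantage_n3():
    """PO 1 starts with a large amplitude advantage, all phases locked."""
    return ReducedState(phi=np.zeros(3), omega0=5.0,
                        a=np.array([13.0, 9.0, 1.0]))


@pytest.fixture(scope="session")
def traj_n3_stationary(params_n3):
    """Reference run converging to the stationary winner point."""
    s0 = ReducedState(phi=np.zeros(3), omega0=5.0,
                      a=np.array([13.0, 9.0, 1.0]))
    return integrate(params_n3, s0, 100.0)


@pytest.fixture(scope="session")
def traj_n3_one_running(coupling_default):
    """One loser detuned beyond |b|: a limit-cycle attractor."""
    p = ModelParams(omega=np.array([5.0, 5.5, 3.5]), b=-1.0,
                    coupling=coupling_default)
    s0 = ReducedState(phi=np.zeros(3), omega0=5.0,
                      a=np.array([13.0, 9.0, 1.0]))
    return p, integrate(p, s0, 100.0)


def full_state_n3():
    return FullState(theta0=0.0, theta=np.zeros(3), omega0=5.0,
                     a=np.array([13.0, 9.0, 1.0]))
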