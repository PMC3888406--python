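import numpy as np
import pytest

from ead2d.ionic_model import find_rest_state, make_params


@pytest.fixture(scope="session")
def baseline_params():
    return make_params()


@pytest.fixture(scope="session")
def ead_params():
    # inside the single-EAD region of the (G_CaL, G_Ks) phase diagram
    return make_params(mult_CaL=5.0, mult_Ks=0.6)


@pytest.fixture(scope="session")
def osc_params():
    # oscillatory regime whose single-cell period matches the reported
    # 6 Hz voltage oscillation
    from ead2d.regimes import OSC_POINT
    return make_params(**OSC_POINT)


@pytest.fixture(scope="session")
def rest_state(baseline_params):
    return find_rest_state(baseline_params)


@pytest.fixture(scope="session")
def mid_ap_state(baseline_params):
    """A state 150 ms into an action potential (gates well off rest)."""
    from ead2d import _kernels
    from ead2d.ionic_model import N_STATE, CellState

    S = find_rest_state(baseline_params).to_vector().reshape(1, N_STATE)
    _kernels.advance(S, baseline_params, 0.02, 100, np.array([20.0]))
    _kernels.advance(S, baseline_params, 0.02, 7400, np.array([0.0]))
    return CellState.from_vector(S[0])
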