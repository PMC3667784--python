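import numpy as np
import pytest
from hypothesis import settings

import invadosim as iv
from invadosim.experiments import m14a_weights, run_core, sweep_timp2

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return iv.KineticParameters()


@pytest.fixture(scope="session")
def core_net(params):
    return iv.build_core_network(params, pools="single")


@pytest.fixture(scope="session")
def core_model(core_net):
    return iv.compile_network(core_net)


@pytest.fixture(scope="session")
def core_weights(core_net):
    return m14a_weights(core_net)


@pytest.fixture(scope="session")
def core_traj_100(params):
    """Closed-model trajectory at TIMP-2 = 100 nM (Fig 1C conditions)."""
    return run_core(params, timp2=100.0)


@pytest.fixture(scope="session")
def core_sweep(params):
    """Full TIMP-2 titration of the closed model (shared across tests)."""
    return sweep_timp2(params=params)


@pytest.fixture(scope="session")
def turnover_model(params):
    import invadosim.turnover as tv

    return tv.build_turnover_model(params)


def rel_diff(a, b, floor=1e-12):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
    return np.max(np.abs(a - b) / scale)
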