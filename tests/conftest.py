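import numpy as np
import pytest

from epileptornet import (
    CouplingParameters,
    IntegrationConfig,
    NodeParameters,
    equilibrium_state,
    simulate,
    single_node_connectome,
    synthetic_connectome,
)


@pytest.fixture(scope="session")
def toy_connectome():
    return synthetic_connectome(4, seed=1)


@pytest.fixture(scope="session")
def base_params():
    return NodeParameters(x0=-2.5, a=1.5, p=0.5)


@pytest.fixture(scope="session")
def equilibrium(base_params):
    return equilibrium_state(base_params)


def run_single_node(x0, a=1.74, p=0.7, b2=4.0, duration=300.0, seed=1,
                    noise=True, initial_state=None):
    """Shared helper: one isolated node, returning the trajectory."""
    params = NodeParameters(x0=x0, a=a, p=p, b2=b2)
    cfg = IntegrationConfig(
        duration=duration, discard=20.0, seed=seed,
        noise_x2y2=0.00025 if noise else 0.0,
        noise_x3=0.02 if noise else 0.0,
    )
    ic = None if initial_state is None else np.asarray(initial_state)[None, :]
    return simulate(single_node_connectome(), params, CouplingParameters(),
                    cfg, initial_state=ic)
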