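import numpy as np
import pytest

import driftlab as dl


@pytest.fixture(scope="session")
def toy():
    """The two-neuron worked example task and its η frame."""
    cfg, task = dl.toy_task()
    frame = dl.build_extended_basis(task.X)
    return cfg, task, frame


@pytest.fixture(scope="session")
def methods_net():
    return dl.NetworkConfig()  # Nx=15, Ny=12, Nz=1, P=8, alpha=5


@pytest.fixture(scope="session")
def methods_task(methods_net):
    return dl.generate_task(methods_net, seed=1)


@pytest.fixture(scope="session")
def learned_state(methods_net, methods_task):
    """A state on the solution space of the standard-size task."""
    return dl.learn_solution(methods_task, methods_net)
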