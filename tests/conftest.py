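import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session", autouse=True)
def _warm_kernel():
    """Compile the population kernel once so per-test timings are honest."""
    from ecdna.simulate import SimulationParams, StopCondition, simulate_leaf_copies

    simulate_leaf_copies(SimulationParams(stop=StopCondition(target_cells=10), seed=0))
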