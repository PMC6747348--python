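import numpy as np
import pytest

from methylsubtypes.datasets import SimulationConfig, generate_dataset
from methylsubtypes.io import BetaMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A 254-sample, 200-probe cohort with 15 planted informative probes."""
    return generate_dataset(
        SimulationConfig(n_probes=200, n_informative=15, effect=0.35, seed=11)
    )


@pytest.fixture
def tiny_matrix():
    """A hand-sized two-class matrix for I/O and error-path tests."""
    rng = np.random.default_rng(3)
    values = rng.uniform(0.1, 0.9, size=(4, 5))
    return BetaMatrix(
        values,
        [f"S{i}" for i in range(4)],
        [f"cg{i:08d}" for i in range(5)],
        np.array(["a", "a", "b", "b"], dtype=object),
    )
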