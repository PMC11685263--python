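import numpy as np
import pytest

import tmcsim as tmc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def replication():
    """One moderately collinear replication used across mediation tests."""
    c = tmc.SimulationCondition(0.7, 0.7, 0.3, 0.5)
    return tmc.generate_replication(c, (42, 0, 0))
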