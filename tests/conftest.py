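import numpy as np
import pytest

import dexval as dx


@pytest.fixture
def worked_example():
    """Single-gene paired fixture: x' = (0,1,1), x = (2,0,-2), d = (-2,1,3)."""
    return dx.worked_example_fixture()


@pytest.fixture
def paired_data_pi09():
    """Paired hierarchical-mixture dataset, m=5000, true pi0 = 0.9."""
    cfg = dx.SimulationConfig(m=5000, n=6, n_prime=6, pi0=0.9, paired=True, seed=42)
    return dx.generate(cfg)


@pytest.fixture
def small_unpaired():
    cfg = dx.SimulationConfig(m=50, n=4, n_prime=4, pi0=0.8, paired=False, seed=5)
    return dx.generate(cfg)[0]
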