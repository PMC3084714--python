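import numpy as np
import pytest

import chemonav as cn


@pytest.fixture
def desens():
    return cn.table1_desensitizable()


@pytest.fixture
def nondesens():
    return cn.table1_nondesensitizable()


@pytest.fixture
def single_env():
    """One canonical 17.6 nM power-gradient source at the origin."""
    return cn.LigandEnvironment([cn.PowerGradientField("L")])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
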