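import numpy as np
import pytest

from stpphase import StimulusParams, SynapticConfig, TheoryParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def theory_params():
    """The standard operating point: 30 +/- 20 Hz drive, P_v = 0.25,
    tau_rec = 0.5 s, f = 1 Hz."""
    return TheoryParams()


@pytest.fixture
def stim_params():
    return StimulusParams()


@pytest.fixture
def syn_config():
    return SynapticConfig()
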