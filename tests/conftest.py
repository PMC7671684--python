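import numpy as np
import pytest

from capsgate import ChannelModel

#: WT capsaicin gating constants implied by Po_max = 0.94 and EC50 = 0.14 µM.
WT_PO_MAX = 0.94
WT_EC50_UM = 0.14
WT_L = WT_PO_MAX / (1.0 - WT_PO_MAX)
WT_KD_UM = WT_EC50_UM * (1.0 + WT_L)


@pytest.fixture
def wt_model() -> ChannelModel:
    """Wild-type capsaicin three-state parameterization (g = 100 pS at +80 mV)."""
    return ChannelModel(K_D=WT_KD_UM, L=WT_L, g=100.0, E_rev=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20201109)
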