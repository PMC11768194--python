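import numpy as np
import pytest

from breadtex.mixolab import MixolabParameters
from breadtex.synthetic import ChopinProtocol


@pytest.fixture
def control_params() -> MixolabParameters:
    """The control-run landmark vector used throughout the round-trip tests."""
    return MixolabParameters(
        t_hydr=3.63,
        t1=7.08,
        c1=1.10,
        water_absorption=62.8,
        amplitude=0.073,
        stability=6.97,
        slope_alpha=-0.095,
        c2=0.52,
        slope_beta=0.110,
        c3=1.61,
        t3=21.7,
        gelling_mid=66.0,
        c4=1.29,
        c5=1.89,
    )


@pytest.fixture
def protocol() -> ChopinProtocol:
    return ChopinProtocol()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
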