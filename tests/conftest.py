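import numpy as np
import pytest

from schaffer.stp import STPParams


@pytest.fixture
def control_params() -> STPParams:
    return STPParams(U=0.15, tau_in=1.0, tau_rec=50.0, tau_facil=200.0, A=1.0)


@pytest.fixture
def abeta_params() -> STPParams:
    return STPParams(U=0.36, tau_in=1.0, tau_rec=50.0, tau_facil=200.0, A=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
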