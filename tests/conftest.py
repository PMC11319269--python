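import numpy as np
import pytest

from signalfate.fate_switch import SwitchParams, stem_state
from signalfate.signal_fields import RDParams


@pytest.fixture(scope="session")
def rd_default() -> RDParams:
    """The study's reaction-diffusion constants (spot-family channel)."""
    return RDParams()


@pytest.fixture(scope="session")
def sw_default() -> SwitchParams:
    return SwitchParams()


@pytest.fixture(scope="session")
def stem_xy(sw_default):
    """Baseline stem attractor, shared across tests (it is re-derived from
    the parameters, not hard-coded)."""
    return stem_state(sw_default)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
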