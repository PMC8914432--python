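import numpy as np
import pytest

from radioresponse import RCRParameters, panel_fixture


@pytest.fixture
def toy_params() -> RCRParameters:
    """A curve with both RCR terms active (used across modules)."""
    return RCRParameters(a=0.4, b=0.8, c=1.2)


@pytest.fixture
def pure_exponential() -> RCRParameters:
    """Degenerate single-exponential curve: S(d) = exp(-0.5 d)."""
    return RCRParameters(a=0.5, b=0.0, c=1.0)


@pytest.fixture(scope="session")
def panel():
    return panel_fixture()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220225)
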