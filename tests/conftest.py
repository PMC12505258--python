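import numpy as np
import pytest

from ipdsim import WeibullParams, build_model


@pytest.fixture(scope="session")
def model():
    """Default acyclovir-parameterized PBPK model."""
    return build_model()


@pytest.fixture(scope="session")
def ref_release():
    """A realistic 800 mg reference release curve (Wmax fixed at 60.75%)."""
    return WeibullParams(alpha=30.0, beta=1.5, wmax=60.75)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)
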