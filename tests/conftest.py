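import numpy as np
import pytest

from tissuetension import MagneticContext


@pytest.fixture(scope="session")
def ctx() -> MagneticContext:
    """Magnetic calibration used across tests: M_V 1000 A/m, grad B 170 T/m."""
    return MagneticContext(m_v=1000.0, grad_b=170.0, b_field_mt=530.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
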