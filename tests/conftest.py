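import numpy as np
import pytest

from spo2delta import ReferenceLine


@pytest.fixture(scope="session")
def line():
    """A plausible hypoxia reference line (negative slope)."""
    return ReferenceLine(slope=-0.035, intercept=3.55, r_squared=0.999,
                         n_points=4, fit_mode="group_mean")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
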