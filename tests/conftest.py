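import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from redelim.grids import FESGrid
from redelim.synthetic_data import make_double_well

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def double_well24():
    """Tall symmetric double well: minima at (±1, 0), saddle (0, 0) at 24."""
    return make_double_well(24.0, 1.0, 2.0)


@pytest.fixture(scope="session")
def grid24(double_well24):
    """The 24 kcal/mol double well sampled on a 201×151 grid."""
    x = np.linspace(-2.0, 2.0, 201)
    y = np.linspace(-1.5, 1.5, 151)
    values = double_well24.value((x[:, None], y[None, :]))
    return FESGrid(x=x, y=y, values=values)
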