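import numpy as np
import pytest

from micropredict.datatypes import Curve
from micropredict.fitting import growth_curve_log10, inhibition_curve_log10


@pytest.fixture
def rng():
    return np.random.default_rng(20250910)


@pytest.fixture
def baranyi_curve():
    """Noise-free Baranyi curve at 20 degC (log10 scale)."""
    t = np.linspace(0.0, 60.0, 20)
    y = np.asarray(growth_curve_log10("baranyi", t, 3.0, 9.0, 0.2, 5.0))
    return Curve(times=t, values=y, condition=20.0)


@pytest.fixture
def weibull_curve():
    """Noise-free Weibull survival curve at 50 mg/L."""
    t = np.array([0.0, 15.0, 30.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0])
    y = np.asarray(inhibition_curve_log10("weibull", t, (7.0, 20.43, 0.33)))
    return Curve(times=t, values=y, condition=50.0, condition_name="chlorine")
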