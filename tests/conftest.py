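import numpy as np
import pytest

from cocmatrix.nanopore import CalibrationCurve


@pytest.fixture(scope="session")
def power_law_cal() -> CalibrationCurve:
    """area = 1e-5 * mw (pA*s per kDa), spanning 50-8000 kDa."""
    return CalibrationCurve.from_power_law(1e-5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
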