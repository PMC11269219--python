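import numpy as np
import pytest

from radiclemorph import CalibrationRatio, RadicleSpec, calibration_ratio


@pytest.fixture
def cal_60() -> CalibrationRatio:
    """25 cm field imaged at 1500 px: R = 1/60 cm per pixel."""
    return calibration_ratio(25, 1500)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def horizontal_bar_spec() -> RadicleSpec:
    """Straight horizontal centerline, 100 px long, unit thickness."""
    return RadicleSpec(((50.0, 20.0), (50.0, 120.0)), 1, (100, 200), (0, 0))
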