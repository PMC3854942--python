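import numpy as np
import pytest

from magflux.calibration import CalibrationConstants
from magflux.model import CellState, ExchangerParams, LeakPumpParams
from magflux.observe import Probe
from magflux.protocols import extrusion_protocol


@pytest.fixture
def exch():
    """A modest wild-type exchanger used by unit tests."""
    return ExchangerParams(vmax_efflux=3.0, ka_na=50.0, n_hill=2.0,
                           km_mg=1.0, stoich=2, activity_scale=1.0)


@pytest.fixture
def no_leak():
    return LeakPumpParams(p_mg_channel=0.0, p_na_leak=0.0, na_pump_rate=0.0)


@pytest.fixture
def loaded():
    return CellState(mg_i=3.0, na_i=10.0)


@pytest.fixture
def schedule():
    return extrusion_protocol()


@pytest.fixture
def example_calib():
    """The worked-example calibration geometry used in hand calculations."""
    return CalibrationConstants(probe=Probe.MAGFURA2, kd=1.5, q=0.5,
                                rmin=0.4, rmax=3.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
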