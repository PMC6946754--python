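import numpy as np
import pytest

from ptrscreen import (DriftConditions, InstrumentParams, IonSource,
                       QuantParams, RunConfig, simulate_spectrum)


@pytest.fixture(scope="session")
def drift():
    return DriftConditions()


@pytest.fixture(scope="session")
def qp():
    return QuantParams()


@pytest.fixture(scope="session")
def tiny_instrument():
    """Small, fast instrument covering m/z 15-80 (enough for the primary
    isotopologue, acetone calibrant and isoprene)."""
    return InstrumentParams(calib_a=6000.0, calib_t0=900.0,
                            mz_range=(15.0, 80.0), dead_time_bins=0)


@pytest.fixture(scope="session")
def standard_ions():
    return [
        IonSource("H3O+", count_rate=1e6, primary=True),
        IonSource("C3H7O+", count_rate=2000.0),
        IonSource(69.0699, ppbv=200.0),
    ]


@pytest.fixture(scope="session")
def tiny_spectrum(standard_ions, tiny_instrument, qp, drift):
    return simulate_spectrum(standard_ions, tiny_instrument, 30.0, qp, drift,
                             seed=7, vial_id="V1")


@pytest.fixture(scope="session")
def tiny_config(tiny_instrument):
    cfg = RunConfig()
    cfg.instrument = tiny_instrument
    cfg.reference_ions = ["H3O18+", "C3H7O+"]
    cfg.peaks.mz_bounds = (15.0, 80.0)
    return cfg
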