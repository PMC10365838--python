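"""Shared fixtures: the default model and its calibrated ramp runs.

The heavy simulations (equilibration, calibration, the mechanism-dissection
trio, the dt-refinement runs) are session-scoped so each is computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ca1ramp.engine import (
    Protocol,
    calibrate_ramp_amplitude,
    default_model,
    run,
    run_mechanism_conditions,
)
from ca1ramp.synthetic import RampSpec

RAMP_PEAK_MS = 1000.0


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def control_cal(model):
    return calibrate_ramp_amplitude(model, Protocol(mode="control", ramp=RampSpec()))


@pytest.fixture(scope="session")
def cch_cal(model):
    return calibrate_ramp_amplitude(model, Protocol(mode="cch", ramp=RampSpec()))


@pytest.fixture(scope="session")
def mechanism_runs(model, cch_cal):
    return run_mechanism_conditions(
        model, Protocol(mode="cch", ramp=RampSpec()), amplitude=cch_cal.amplitude
    )


@pytest.fixture(scope="session")
def refined_runs(model, control_cal, cch_cal):
    """Each calibrated ramp re-run at half the default time step."""
    out = {}
    for mode, cal in (("control", control_cal), ("cch", cch_cal)):
        proto = Protocol(mode=mode, ramp=RampSpec(amplitude=cal.amplitude), dt=0.0125)
        out[mode] = run(model, proto)
    return out
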