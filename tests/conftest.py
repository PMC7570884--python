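import numpy as np
import pytest

from glybolus.patient import CGMTrace, PatientParams
from glybolus.therapy import TherapyParams, derive_therapy


@pytest.fixture(scope="session")
def adult():
    return PatientParams.nominal_adult()


@pytest.fixture(scope="session")
def adult_therapy(adult):
    return derive_therapy(adult)


@pytest.fixture
def simple_therapy():
    """Round-number therapy settings convenient for hand calculations."""
    return TherapyParams(icr=10.0, isf=30.0, target_glucose=120.0, t_iob=240.0)


def constant_trace(value, n=60, spacing=5.0, start=0.0):
    times = start + spacing * np.arange(1, n + 1)
    return CGMTrace(times, np.full(n, float(value)))


@pytest.fixture
def make_trace():
    return constant_trace
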