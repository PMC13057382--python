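import numpy as np
import pytest

from ventsync.config import DEFAULT_CONFIG
from ventsync.simulator import (AsynchronyProfile, PatientModel, VentSettings,
                                simulate_session)


@pytest.fixture(scope="session")
def cfg():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def clean_session():
    """Zero-injection conventional session: every breath is synchronous."""
    profile = AsynchronyProfile(rates_per_min={k: 0.0 for k in
                                               ("IE", "AT", "DB", "TD", "EC", "LC")})
    return simulate_session(PatientModel(), VentSettings(), profile,
                            duration_s=300.0, seed=7)


@pytest.fixture(scope="session")
def default_session():
    """Conventional session with default injection rates."""
    return simulate_session(PatientModel(), VentSettings(),
                            AsynchronyProfile(), duration_s=600.0, seed=1)


@pytest.fixture(scope="session")
def quiet_patient():
    """Low respiratory rate, long expiration: breaths empty completely."""
    return PatientModel(neural_rate_bpm=18.0, neural_ti_s=0.7)
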