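import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seqpool as sp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spm():
    return sp.SequentialPoolModel()


@pytest.fixture(scope="session")
def ppm():
    return sp.ParallelPoolModel()


@pytest.fixture(scope="session")
def spm_flash(spm):
    """The reference uncaging experiment: 0.5 -> 25 uM step on the
    wild-type sequential model, fitted over a 5 s window."""
    return sp.flash_experiment(spm)


@pytest.fixture(scope="session")
def double_flash_isi8(spm, ppm):
    """Double-uncaging recovery at 8 s inter-stimulus interval for the
    sequential and the parallel model (shared: the slowest simulations
    in the suite)."""
    return {
        "spm": sp.double_flash_recovery(spm, [8.0]),
        "ppm": sp.double_flash_recovery(ppm, [8.0]),
    }


@pytest.fixture(scope="session")
def clean_synthetic_burst():
    """Noise-free trace generated exactly from the burst fit function
    (A1=60 fF, tau1=20 ms, A2=50 fF, tau2=200 ms, A3=10 fF/s)."""
    t = np.arange(0.0, 5.0 + 5e-4, 1e-3)
    truth = dict(A0=5.0, t0=0.0, A1=60.0, tau1=0.02, A2=50.0, tau2=0.2, A3=10.0)
    y = sp.burst_curve(t, truth["t0"], truth["A0"], truth["A1"],
                       truth["tau1"], truth["A2"], truth["tau2"], truth["A3"])
    return t, y, truth
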