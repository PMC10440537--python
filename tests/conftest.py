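import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prtms.eeg_io import EEGRecording, standard_montage
from prtms.spectral import FREQ_GRID, PowerSpectrum

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture
def gaussian_spectrum():
    """Factory: single-channel spectrum = Gaussian bump + optional baseline."""

    def make(center=10.0, amp=2.0, sigma=0.5, baseline=0.0, lead="x"):
        power = baseline + amp * np.exp(
            -((FREQ_GRID - center) ** 2) / (2.0 * sigma ** 2))
        return PowerSpectrum(freqs=FREQ_GRID.copy(), power=power[None, :],
                             leads=(lead,), fs=250.0)

    return make


@pytest.fixture
def white_recording():
    """Factory: 19-lead white-noise recording (stationary, artifact-free)."""

    def make(duration_s=40.0, fs=125.0, sd=20.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(duration_s * fs)
        return EEGRecording(data=rng.normal(0.0, sd, size=(19, n)), fs=fs)

    return make
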