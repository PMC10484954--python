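import numpy as np
import pytest

from oxyphase import AcquisitionSettings, GroundTruth, SternVolmerModel

F_R = 1625.0


@pytest.fixture
def settings():
    """Device-like acquisition settings with a fixed noise seed."""
    return AcquisitionSettings(seed=12345)


@pytest.fixture
def quantized_settings():
    return AcquisitionSettings(adc_bits=12, adc_vref_v=5.0, seed=12345)


@pytest.fixture
def truth_60us():
    return GroundTruth(lifetime_s=60e-6, amplitude_v=1.0, background_v=0.05, noise_sd_v=0.0)


@pytest.fixture
def sv_model():
    """Ground-truth calibration parameters used across the synthetic studies."""
    return SternVolmerModel(
        tau0_s=60e-6, k0_per_mmHg=0.02, kT_per_mmHg_c=1e-4, f_s=5e-6, tc_c=24.0
    )


def dft_phase(times_s, voltages_v, f_hz):
    """Independent oracle: phase of the discrete Fourier projection at f_hz.

    Valid for uniformly sampled data covering an integer number of periods,
    where the {1, cos, sin} regressors are exactly orthogonal.
    """
    w = 2.0 * np.pi * f_hz * np.asarray(times_s)
    y = np.asarray(voltages_v)
    b1 = 2.0 / y.size * float(y @ np.cos(w))
    b2 = 2.0 / y.size * float(y @ np.sin(w))
    return float(np.arctan2(b2, b1))


def integer_period_times(f_hz=F_R, periods=10, per_period=64):
    """Uniform time base spanning exactly `periods` modulation periods."""
    n = periods * per_period
    fs = per_period * f_hz
    return np.arange(n) / fs
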