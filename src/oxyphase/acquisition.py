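"""Core data containers for modulated-excitation lifetime acquisitions.

The measurement principle is frequency-domain phase fluorometry: the
excitation LED is driven sinusoidally at a reference frequency ``f_r`` and
the phosphorescent emission of an oxygen-quenched porphyrin lags it by a
phase ``delta_theta`` with ``tan(delta_theta) = 2*pi*f_r*tau``, where ``tau``
is the (mono-exponential) phosphorescence lifetime.  These containers hold
one channel's sampled waveform plus the acquisition settings that produced
it, and the per-acquisition ground truth used by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionSettings",
    "GroundTruth",
    "ModulatedTrace",
    "CHANNELS",
]

CHANNELS = ("reference", "phosphorescence", "dark")

# Device timing: 500 lit samples over the 150 ms LED-on window.
DEFAULT_MODULATION_HZ = 1625.0
DEFAULT_N_BACKGROUND = 100
DEFAULT_N_SIGNAL = 500
DEFAULT_SAMPLE_RATE_HZ = DEFAULT_N_SIGNAL / 0.150


@dataclass(frozen=True)
class AcquisitionSettings:
    """Acquisition configuration for one lifetime measurement.

    Parameters
    ----------
    modulation_hz
        Reference (excitation modulation) frequency ``f_r`` in Hz.
    n_background
        Number of dark (LED off) samples averaged for background removal.
    n_signal
        Number of lit samples per channel.
    sample_rate_hz
        ADC sampling frequency in Hz; must exceed twice the modulation
        frequency (Nyquist).
    adc_bits, adc_vref_v
        Optional quantizer description (bit depth and reference voltage);
        both must be given for quantization to apply.
    seed
        Optional seed for the simulator's noise stream.
    """

    modulation_hz: float = DEFAULT_MODULATION_HZ
    n_background: int = DEFAULT_N_BACKGROUND
    n_signal: int = DEFAULT_N_SIGNAL
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    adc_bits: Optional[int] = None
    adc_vref_v: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.modulation_hz > 0:
            raise ValueError("modulation_hz must be positive")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if self.n_signal < 4:
            raise ValueError("n_signal must be >= 4")
        if not self.sample_rate_hz > 2 * self.modulation_hz:
            raise ValueError(
                "sample_rate_hz must exceed twice modulation_hz "
                f"({self.sample_rate_hz} <= {2 * self.modulation_hz})"
            )
        if (self.adc_bits is None) != (self.adc_vref_v is None):
            raise ValueError("adc_bits and adc_vref_v must be set together")
        if self.adc_bits is not None and self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")
        if self.adc_vref_v is not None and not self.adc_vref_v > 0:
            raise ValueError("adc_vref_v must be positive")

    @property
    def period_s(self) -> float:
        """Modulation period ``T = 1/f_r`` in seconds."""
        return 1.0 / self.modulation_hz


@dataclass(frozen=True)
class GroundTruth:
    """Known simulator truth for one emitter state.

    ``amplitude_v`` is the fundamental emission amplitude of the fully
    unquenched phosphor; ``bleach_per_acq`` multiplies it once per completed
    acquisition to emulate photobleaching.
    """

    lifetime_s: float
    amplitude_v: float = 1.0
    background_v: float = 0.05
    noise_sd_v: float = 0.0
    bleach_per_acq: float = 1.0

    def __post_init__(self) -> None:
        if self.lifetime_s < 0:
            raise ValueError("lifetime_s must be >= 0")
        if self.amplitude_v < 0:
            raise ValueError("amplitude_v must be >= 0")
        if self.noise_sd_v < 0:
            raise ValueError("noise_sd_v must be >= 0")
        if not 0 < self.bleach_per_acq <= 1:
            raise ValueError("bleach_per_acq must be in (0, 1]")

    def replace(self, **changes) -> "GroundTruth":
        return replace(self, **changes)


@dataclass(frozen=True)
class ModulatedTrace:
    """One channel's sampled time/voltage series for a single acquisition."""

    channel: str
    times_s: np.ndarray
    voltages_v: np.ndarray
    settings: AcquisitionSettings = field(default_factory=AcquisitionSettings)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.voltages_v, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times_s and voltages_v must be equal-length 1-D arrays")
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
            raise ValueError("trace contains non-finite values")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "voltages_v", v)

    def __len__(self) -> int:
        return self.times_s.size

    def with_voltages(self, voltages_v: np.ndarray) -> "ModulatedTrace":
        return ModulatedTrace(self.channel, self.times_s, np.asarray(voltages_v, float), self.settings)

    def with_times(self, times_s: np.ndarray) -> "ModulatedTrace":
        return ModulatedTrace(self.channel, np.asarray(times_s, float), self.voltages_v, self.settings)
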