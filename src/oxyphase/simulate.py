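"""Virtual instrument: synthetic reference and phosphorescence traces.

Generates the three channels a real acquisition produces — a dark
(background) trace, the electrically sampled sinusoidal reference, and the
phosphorescence channel — from a known ground truth, so the whole extraction
and calibration chain can be exercised without hardware.

The emitter is modelled as a single-exponential luminophore under sinusoidal
excitation at ``f_r``: its emission is a pure fundamental, phase-lagged by
``delta_theta = arctan(2*pi*f_r*tau)`` and attenuated by the demodulation
factor ``m(tau) = 1/sqrt(1 + (2*pi*f_r*tau)**2)``.  Additive noise is i.i.d.
Gaussian per sample; the reference channel is noise-free by default (it is a
sampled drive signal, not a photodetector output).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .acquisition import AcquisitionSettings, GroundTruth, ModulatedTrace
from .calibration import SternVolmerModel, predict_lifetime

__all__ = [
    "phase_lag",
    "demodulation_factor",
    "simulate_dark",
    "simulate_pair",
    "quantize",
    "truth_from_model",
    "simulate_calibration_points",
    "REFERENCE_OFFSET_V",
    "REFERENCE_AMPLITUDE_V",
]

# Reference-channel drive conventions (the device's are unspecified): a
# 2.5 V offset, 2.0 V amplitude sinusoid sits comfortably in a 0-5 V ADC span.
REFERENCE_OFFSET_V = 2.5
REFERENCE_AMPLITUDE_V = 2.0


def phase_lag(lifetime_s: float, modulation_hz: float) -> float:
    """Phase lag arctan(2*pi*f_r*tau) of a single-exponential emitter, rad."""
    return float(np.arctan(2.0 * np.pi * modulation_hz * lifetime_s))


def demodulation_factor(lifetime_s: float, modulation_hz: float) -> float:
    """Modulation-depth attenuation 1/sqrt(1 + (2*pi*f_r*tau)**2)."""
    w_tau = 2.0 * np.pi * modulation_hz * lifetime_s
    return float(1.0 / np.sqrt(1.0 + w_tau * w_tau))


def _rng(settings: AcquisitionSettings, stream: int) -> np.random.Generator:
    # Separate child streams so dark/pair draws are independent but both
    # reproducible from the one settings seed.
    if settings.seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(settings.seed).spawn(stream + 1)[stream])


def simulate_dark(settings: AcquisitionSettings, truth: GroundTruth) -> ModulatedTrace:
    """Dark (LED off) acquisition: background level plus Gaussian noise."""
    rng = _rng(settings, 0)
    t = np.arange(settings.n_background) / settings.sample_rate_hz
    v = np.full(settings.n_background, truth.background_v, dtype=float)
    if truth.noise_sd_v > 0:
        v = v + rng.normal(0.0, truth.noise_sd_v, size=v.size)
    return ModulatedTrace("dark", t, v, settings)


def simulate_pair(
    settings: AcquisitionSettings, truth: GroundTruth, acq_index: int = 0
) -> Tuple[ModulatedTrace, ModulatedTrace]:
    """Simulate one lit acquisition: (reference, phosphorescence) traces.

    Both channels share a time base of ``n_signal`` samples at
    ``sample_rate_hz``.  The reference is a zero-phase cosine at the
    modulation frequency; the phosphorescence channel carries the
    lifetime-dependent phase lag and demodulation, scaled by the
    photobleaching factor ``bleach_per_acq ** acq_index``.
    """
    if acq_index < 0:
        raise ValueError("acq_index must be >= 0")
    rng = _rng(settings, 1)
    fr = settings.modulation_hz
    t = np.arange(settings.n_signal) / settings.sample_rate_hz
    omega_t = 2.0 * np.pi * fr * t

    ref = REFERENCE_OFFSET_V + REFERENCE_AMPLITUDE_V * np.cos(omega_t)

    dtheta = phase_lag(truth.lifetime_s, fr)
    amp = truth.amplitude_v * truth.bleach_per_acq**acq_index * demodulation_factor(truth.lifetime_s, fr)
    phos = truth.background_v + amp * np.cos(omega_t - dtheta)
    if truth.noise_sd_v > 0:
        phos = phos + rng.normal(0.0, truth.noise_sd_v, size=phos.size)

    return (
        ModulatedTrace("reference", t, ref, settings),
        ModulatedTrace("phosphorescence", t, phos, settings),
    )


def quantize(trace: ModulatedTrace) -> ModulatedTrace:
    """Round voltages to the trace's ADC grid and clip to [0, vref].

    The least significant bit is ``vref / 2**bits`` (1.2207 mV for the
    device's 5 V / 12-bit converter).
    """
    s = trace.settings
    if s.adc_bits is None or s.adc_vref_v is None:
        raise ValueError("quantize requires adc_bits and adc_vref_v in the trace settings")
    lsb = s.adc_vref_v / 2**s.adc_bits
    v = np.clip(np.round(trace.voltages_v / lsb) * lsb, 0.0, s.adc_vref_v)
    return trace.with_voltages(v)


def truth_from_model(
    model: SternVolmerModel,
    pO2_mmHg: float,
    temp_c: float,
    template: GroundTruth,
) -> GroundTruth:
    """Ground truth for a given oxygen tension and temperature.

    The lifetime follows the temperature-compensated Stern-Volmer relation.
    The emission amplitude is scaled by ``(tau - f)/tau0`` — intensity
    proportional to the quenched (oxygen-dependent) part of the lifetime —
    so intensity and lifetime co-vary the way a quenched phosphor's do.
    This coupling is a simulator convention, not a calibration formula.
    """
    if pO2_mmHg < 0:
        raise ValueError("pO2_mmHg must be >= 0")
    tau = predict_lifetime(model, pO2_mmHg, temp_c)
    scale = (tau - model.f_s) / model.tau0_s
    return template.replace(lifetime_s=tau, amplitude_v=template.amplitude_v * scale)


def simulate_calibration_points(
    model: SternVolmerModel,
    setpoints_mmHg,
    temps_c,
    noise_sd_s: float = 0.5e-6,
    samples_per_setpoint: int = 100,
    cadence_s: float = 3.0,
    seed: Optional[int] = None,
):
    """Synthetic benchtop calibration run: equilibrated lifetime readings.

    Emulates the calibration protocol — the chamber dwells at each gas-mixer
    setpoint long enough to equilibrate, the reference oximeter reads pO2 on
    a fixed cadence (3 s), and each reading pairs a reference pO2 with a
    measured lifetime and chamber temperature.  Lifetimes are the
    Stern-Volmer prediction plus i.i.d. Gaussian noise of SD ``noise_sd_s``
    (default 0.5 us, matching the device's observed lifetime scatter).

    Returns a :class:`pandas.DataFrame` with columns
    ``timestamp_s, lifetime_s, temp_c, pO2_ref_mmHg``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    setpoints = np.atleast_1d(np.asarray(setpoints_mmHg, float))
    temps = np.atleast_1d(np.asarray(temps_c, float))
    # one block of `samples_per_setpoint` readings per (temperature, setpoint)
    p = np.tile(np.repeat(setpoints, samples_per_setpoint), temps.size)
    T = np.repeat(temps, setpoints.size * samples_per_setpoint)
    tau = predict_lifetime(model, p, T) + rng.normal(0.0, noise_sd_s, size=p.size)
    ts = cadence_s * np.arange(p.size)
    return pd.DataFrame({"timestamp_s": ts, "lifetime_s": tau, "temp_c": T, "pO2_ref_mmHg": p})
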