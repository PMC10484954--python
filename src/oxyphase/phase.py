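"""Phase-domain lifetime extraction.

The chain mirrors the device's firmware procedure: average the dark samples,
subtract that background from the lit channels, fold each trace onto a
single modulation period, fit the three-coefficient sinusoid

    y(t) = b0 + b1*cos(2*pi*f_r*t) + b2*sin(2*pi*f_r*t)

by ordinary least squares, recover each channel's phase
theta = atan2(b2, b1) (equivalently arccos(b1/sqrt(b1^2+b2^2)) signed by
b2), and convert the reference-to-emission phase difference to a lifetime
via tau = tan(delta_theta) / (2*pi*f_r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .acquisition import AcquisitionSettings, ModulatedTrace

__all__ = [
    "PhaseFit",
    "LifetimeSample",
    "InfeasiblePhaseError",
    "mean_background",
    "subtract_background",
    "fold_period",
    "fit_sinusoid",
    "phase_from_coefficients",
    "lifetime_from_phases",
    "acquire_lifetime",
]


class InfeasiblePhaseError(ValueError):
    """Phase difference outside [0, pi/2): the tangent conversion is undefined.

    Raised instead of clamping because such values indicate a failed or
    mis-triggered acquisition that callers must see.
    """


@dataclass(frozen=True)
class PhaseFit:
    """Least-squares sinusoid fit for one channel.

    ``beta0`` is the DC term, ``beta1``/``beta2`` the cosine/sine
    coefficients, ``theta_rad`` the recovered phase in (-pi, pi], ``rss``
    the residual sum of squares over ``n_points`` samples.
    """

    beta0: float
    beta1: float
    beta2: float
    theta_rad: float
    rss: float
    n_points: int

    @property
    def amplitude_v(self) -> float:
        return math.hypot(self.beta1, self.beta2)


@dataclass(frozen=True)
class LifetimeSample:
    """One extracted lifetime with its phase difference and context."""

    delta_theta_rad: float
    lifetime_s: float
    temp_c: Optional[float] = None
    timestamp_s: Optional[float] = None


def mean_background(dark: ModulatedTrace) -> float:
    """Arithmetic mean of the dark-channel voltages (volts)."""
    if len(dark) == 0:
        raise ValueError("dark trace is empty")
    return float(np.mean(dark.voltages_v))


def subtract_background(trace: ModulatedTrace, bg_v: float) -> ModulatedTrace:
    """Remove a DC background level; times are untouched."""
    if not math.isfinite(bg_v):
        raise ValueError("background voltage must be finite")
    return trace.with_voltages(trace.voltages_v - bg_v)


def fold_period(trace: ModulatedTrace, modulation_hz: float) -> ModulatedTrace:
    """Map sample times onto one modulation period via t mod (1/f_r).

    Voltages are unchanged and the output is not re-sorted; the sinusoid
    regression does not require ordered abscissae.
    """
    if not modulation_hz > 0:
        raise ValueError("modulation frequency must be positive")
    period = 1.0 / modulation_hz
    return trace.with_times(np.mod(trace.times_s, period))


def fit_sinusoid(trace: ModulatedTrace, modulation_hz: float) -> PhaseFit:
    """OLS fit of a DC + fundamental cosine/sine model at ``modulation_hz``.

    Solves for (b0, b1, b2) against the regressors
    {1, cos(2*pi*f_r*t), sin(2*pi*f_r*t)} and derives the phase.  Raises on
    a rank-deficient design (e.g. all sample times identical).
    """
    if not modulation_hz > 0:
        raise ValueError("modulation frequency must be positive")
    t = trace.times_s
    y = trace.voltages_v
    if t.size < 4:
        raise ValueError("need at least 4 samples to fit the sinusoid")
    omega_t = 2.0 * np.pi * modulation_hz * t
    design = np.column_stack([np.ones_like(t), np.cos(omega_t), np.sin(omega_t)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design: sample times do not span the sinusoid")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    theta = phase_from_coefficients(beta[1], beta[2])
    return PhaseFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        theta_rad=theta,
        rss=float(resid @ resid),
        n_points=int(t.size),
    )


def phase_from_coefficients(beta1: float, beta2: float) -> float:
    """Phase in (-pi, pi] from the cosine/sine coefficients.

    arccos(b1/sqrt(b1^2+b2^2)) alone is ambiguous on [0, pi]; the sign of
    the sine coefficient resolves the quadrant, which is exactly the
    two-argument arctangent.
    """
    if beta1 == 0.0 and beta2 == 0.0:
        raise ValueError("zero amplitude: phase is undefined")
    return math.atan2(beta2, beta1)


def lifetime_from_phases(
    theta_p: float,
    theta_r: float,
    modulation_hz: float,
    temp_c: Optional[float] = None,
    timestamp_s: Optional[float] = None,
) -> LifetimeSample:
    """Convert a phase difference to a lifetime: tau = tan(dtheta)/(2*pi*f_r).

    The difference theta_p - theta_r is wrapped into [0, pi).  Values at or
    beyond pi/2 sit at/past the tangent pole and raise
    :class:`InfeasiblePhaseError`.
    """
    if not modulation_hz > 0:
        raise ValueError("modulation frequency must be positive")
    dtheta = math.fmod(theta_p - theta_r, math.pi)
    if dtheta < 0:
        dtheta += math.pi
    if dtheta >= math.pi / 2:
        raise InfeasiblePhaseError(
            f"phase difference {dtheta:.6f} rad >= pi/2: outside the feasible "
            "first-order response range (acquisition failure?)"
        )
    tau = math.tan(dtheta) / (2.0 * math.pi * modulation_hz)
    return LifetimeSample(
        delta_theta_rad=dtheta, lifetime_s=tau, temp_c=temp_c, timestamp_s=timestamp_s
    )


def acquire_lifetime(
    dark: ModulatedTrace,
    reference: ModulatedTrace,
    phosphorescence: ModulatedTrace,
    settings: AcquisitionSettings,
    fold: bool = True,
    temp_c: Optional[float] = None,
    timestamp_s: Optional[float] = None,
) -> LifetimeSample:
    """Full extraction: background removal, folding, fits, lifetime.

    The reference phase is estimated by the same regression as the emission
    phase (both channels are sampled); no zero-phase assumption is made.
    ``fold=False`` fits the raw, unfolded samples instead — equivalent on
    noise-free data, provided for diagnostics.
    """
    fr = settings.modulation_hz
    bg = mean_background(dark)
    chans = []
    for trace in (reference, phosphorescence):
        work = subtract_background(trace, bg) if trace.channel == "phosphorescence" else trace
        if fold:
            work = fold_period(work, fr)
        chans.append(fit_sinusoid(work, fr))
    theta_r, theta_p = chans[0].theta_rad, chans[1].theta_rad
    return lifetime_from_phases(theta_p, theta_r, fr, temp_c=temp_c, timestamp_s=timestamp_s)
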