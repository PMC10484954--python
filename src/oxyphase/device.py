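"""Analytic constants of the readout electronics.

Two small closed forms tie the software to the hardware it emulates: the RC
low-pass corner frequency that sets the nominal modulation frequency, and
the ADC's voltage resolution per code.
"""

from __future__ import annotations

import math

__all__ = ["rc_corner_frequency", "adc_lsb_mv"]


def rc_corner_frequency(resistance_ohm: float, capacitance_f: float) -> float:
    """Corner frequency f = 1/(2*pi*R*C) of a first-order RC low-pass, Hz.

    With the device's R = 980 ohm and C = 0.1 uF this is ~1624 Hz, matching
    the nominal 1625 Hz modulation frequency to within 0.1%.
    """
    if not resistance_ohm > 0 or not capacitance_f > 0:
        raise ValueError("resistance and capacitance must be positive")
    return 1.0 / (2.0 * math.pi * resistance_ohm * capacitance_f)


def adc_lsb_mv(vref_v: float, bits: int) -> float:
    """ADC least-significant-bit size in millivolts: 1000 * vref / 2**bits.

    A 5 V reference on a 12-bit converter gives 1.2207 mV/bit (1.2 mV/bit
    at two significant figures).
    """
    if not vref_v > 0:
        raise ValueError("vref_v must be positive")
    if bits < 1:
        raise ValueError("bits must be >= 1")
    return 1000.0 * vref_v / 2**int(bits)
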