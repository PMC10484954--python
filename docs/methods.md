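# Methods

## Measurement model

The package models a fiber-optic oxygen sensor read out by frequency-domain
phase fluorometry. A single-exponential phosphor under sinusoidal excitation
at frequency f_r emits a pure fundamental, lagged by Δθ = arctan(2π f_r τ)
and attenuated by the demodulation factor m(τ) = 1/√(1 + (2π f_r τ)²).
Harmonic content of the drive is not modelled: with adequate low-pass
filtering of the LED drive the fundamental-only regression is sufficient,
and harmonic terms are left as an extension point of `fit_sinusoid` rather
than implemented.

The simulator (`oxyphase.simulate`) produces three channels per
acquisition:

* **dark** — `n_background` samples of the DC background plus noise
  (default 100 samples, emulating the LED-off background average);
* **reference** — a noise-free zero-phase cosine at f_r (it is an
  electrically sampled drive signal, not a photodetector output); its
  offset (2.5 V) and amplitude (2.0 V) are conventions chosen to sit inside
  a 0–5 V ADC span, as the real device's values are not published;
* **phosphorescence** — background + amplitude · bleach^acq_index · m(τ) ·
  cos(2π f_r t − Δθ) + noise.

Defaults mirror the emulated device: f_r = 1625 Hz, 500 lit samples over a
150 ms LED-on window (hence a 3333 Hz sampling rate — the device's actual
ADC rate is not published, so this value is inferred from the two published
timing figures and is configurable), optional 12-bit quantization against a
5 V reference. Noise is additive i.i.d. Gaussian per sample with a
user-set SD — the simplest model consistent with an APD readout; it does
not emulate shot-noise scaling with signal level, 1/f drift, temperature
transients, or trigger jitter. Passing tests therefore demonstrate
algorithmic correctness and noise propagation under this idealization, not
performance on real tissue data.

`truth_from_model` couples emission intensity to lifetime by scaling the
amplitude with (τ − f)/τ0, i.e. intensity proportional to the quenched,
oxygen-dependent part of the lifetime. This reproduces the qualitative
co-increase of phase and intensity at low oxygen and is a simulator
convention only; no calibration computation depends on it.

## Extraction chain

`acquire_lifetime` runs: dark-mean → background subtraction (applied to the
photodetector channel; the regression's DC term absorbs any residual offset,
which is why the chain is provably invariant to common DC shifts) → period
folding `t mod 1/f_r` → OLS fit of {1, cos, sin} regressors → phase
θ = atan2(β2, β1) → τ = tan(θ_p − θ_r)/(2π f_r).

Numerical choices:

* **Quadrant recovery.** The arccos phase formula is ambiguous on [0, π];
  the sign of the sine coefficient disambiguates it, which is the
  two-argument arctangent used here.
* **Folded vs raw fitting.** Whether the device fits the folded single
  period or all raw samples is equivalent for an exact sinusoid model; both
  paths are implemented (`fold=True` default) and tested to agree to 1e-9.
* **Phase wrapping.** θ_p − θ_r is wrapped into [0, π). Values at or past
  π/2 sit at/beyond the tangent pole and raise `InfeasiblePhaseError`
  rather than clamping: such readings indicate a failed acquisition and
  must be visible to callers. A consequence is that noise can push a
  near-zero lag to an error instead of a tiny negative lifetime; that is
  deliberate.
* **Reference phase.** θ_r is estimated by the same regression as θ_p; no
  analytic zero-phase assumption is made, so drive-chain delays cancel in
  the difference.

The lifetime estimate is exactly invariant to amplitude scaling
(photobleaching) and DC offsets on noise-free data, and the sensitivity
dτ/dΔθ = (1 + (2πf_rτ)²)/(2πf_r) grows quadratically with τ: at fixed phase
noise, lifetime precision degrades at long lifetimes (low oxygen maps to
long τ, but the *relative* pO2 resolution is worst at high pO2, where the
Stern–Volmer curve flattens — both behaviours are covered by tests).

## Calibration

`SternVolmerCalibration.fit` performs unweighted nonlinear least squares on
the lifetime scale (no weighting scheme is published for the protocol;
weighting can be added by resampling the input). The 1-D fit estimates
(τ0, k0, f) at a fixed temperature; the 2-D fit adds kT with the reference
temperature TC fixed by the user (conventionally the room-temperature leg,
24 °C). Initialization is deterministic and data-driven: f from the
smallest lifetime at the highest setpoint (shrunk 10% to stay strictly
below all observations), τ0 from the lowest-oxygen lifetime minus f, k0
from a through-origin linear Stern–Volmer fit of τ0/(τ − f) − 1 against
pO2, kT = 0. Bounds keep τ0, k0 > 0 and f ≥ 0.

Inference is standard Gauss–Markov linearization: covariance
σ²(JᵀJ)⁻¹ with σ² = RSS/(n − p), t-based confidence intervals, and a
prediction interval for a new single reading of

    τ̂(x) ± t_{1−α/2, n−p} · σ · √(1 + gᵀ(JᵀJ)⁻¹g),

with g the parameter gradient of the prediction at x. The lifetime-scale
band is mapped through the closed-form inverse to pO2 bounds (lifetime
decreases with oxygen, so the bounds swap); infeasible or negative
inversions are clamped to the physical domain. In the large-n limit the
half-width converges to 1.96σ at the 95% level, and on the pO2 scale the
band widens with oxygen tension because |dτ/dpO2| shrinks as 1/(1+K·pO2)².

`invert_pO2` flags rather than hides edge cases: small negative inversions
from noise are clamped to 0 with flag `"clamped"`; lifetimes at or below
the background offset f return NaN with flag `"infeasible"`; a non-positive
effective quenching constant raises `InvalidRegimeError`.

`bland_altman` uses the conventional mean difference ± 1.96 × sample
(n−1) SD limits of agreement. `relative_error_profile` reports several
summaries (median, mean, 95th percentile, max) of |predicted −
reference|/reference over a pO2 window, because "accuracy ≈ ±10%" style
statements do not pin down a single statistic.

## Synthetic study conditions

The default synthetic calibration emulates the benchtop protocol: setpoints
from `make_schedule` (5 mmHg steps below 20, 10 between 20 and 60, 20 above
60), a 5-minute dwell per setpoint with the reference oximeter sampling
every 3 s (100 readings per setpoint, all taken as equilibrated), at
24/30/36 °C. Ground-truth parameters are τ0 = 60 µs, k0 = 0.02 /mmHg,
f = 5 µs, TC = 24 °C, with lifetime noise SD 0.5 µs; kT = 1e-4 /(mmHg·°C)
is chosen small — about a 6% change in the quenching constant over the
12 °C physiological span — matching a calibration that is only slightly
temperature dependent. Chamber transients, drift during dwells, and
fiber-to-fiber variation are not modelled; separate datasets should be fit
per fiber.

Under these conditions the Monte-Carlo study (200 replicates) shows nominal
95% CI coverage for all four parameters, and the 10–100 mmHg relative-error
profile has a 95th percentile near 8% — consistent with a single-frequency
device accurate to roughly ±10% in that range. One identifiability note:
the background offset f is weakly determined by a 0–100 mmHg span (the
quenching term K·pO2 only reaches ~2, far from the saturation that pins f),
so its *relative* accuracy is several times worse than τ0's or k0's even
though its CI coverage is nominal; spanning higher pO2 or fixing f from a
phosphor-free blank would sharpen it.

## Problem sizes and limitations

The test suite and acceptance script run entirely on synthetic data:
40-point lifetime grids over 1–200 µs for the extraction chain, 200-replicate
Monte-Carlo studies of 3300 calibration points each (11 setpoints × 3
temperatures × 100 readings) for coverage, completing in seconds. The
package does not model the analog electronics (filters, amplifier), LED
spectra, humidity, coating chemistry, or multi-frequency sweeps; frequency
sweeping is a documented direction for improving high-pO2 resolution but is
out of scope here.
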