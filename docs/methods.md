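# Methods

## Array model and conventions

The package models a first-order differential ("delay-and-subtract")
two-microphone array: the rear microphone's signal is delayed by an
algorithm delay τ, scaled by a weight β ≥ 0 and subtracted from the front
signal.  For a far-field plane wave of frequency f at incidence θ
(measured from the endfire axis through the microphones, in degrees over
[−180°, 180°]; computation is in radians) the magnitude response is

    |H(θ, f)| = √(1 + β² − 2β cos(2πf(d cosθ/c + τ))).

Defaults are the CI-scale geometry d = 0.01 m and c = 340 m/s.  0 Hz is
evaluated literally (the cosine term is 1, giving |1 − β|); no limits are
taken.  Named delays: dipole τ = 0, supercardioid τ = 0.342 d/c, cardioid
τ = d/c.  Beam patterns are stored un-normalized; normalizing the 0 Hz
level to 1 is an explicit separate step (degenerate at β = 1) because the
raw and normalized views answer different questions.  The reciprocity
|H(β)| = β|H(1/β)| means only β ≤ 1 needs independent treatment; weights
above 1 are reduced through it everywhere in the compensation module.

The far-field rule (plane-wave propagation beyond two wavelengths,
distance 2c/f) is returned exactly; rounding to two decimals is left to
report formatting.

## Linearized response model

All f→H analysis fixes θ = 0 (on-axis target).  This is the only incidence
under which the endpoint minimizer cos(2π·6000·d/c) = 0.4457 matches the
tabulated turning weight 0.45, so it is treated as the model's defining
convention.

The model interpolates the band endpoint H(β, f_max) piecewise linearly in
β between H₁ = 1 (β = 0), H₂ = H(β_turn, f_max) and H₃ = H(1, f_max), then
joins (0, |1 − β|) to (f_max, endpoint) with a straight line.  `f_max`
defaults to 6000 Hz, the upper edge of the band that matters for speech.
`beta_turn` defaults to the exact minimizer rounded to two decimals — the
resolution at which the weight family is tabulated — and is recomputed
from the geometry, so non-default d, c, τ, f_max remain valid.  With the
default geometry the closed-form slope coefficients are 1.2784e−4 (β ≤
0.45) and 2.1445e−4·β − 3.8974e−5 (β > 0.45) per Hz.  Evaluation above
f_max is permitted (the top filter-bank channel's centre, 6276 Hz, sits
there) but flagged with an `ExtrapolationWarning`.

A degenerate turning weight of 0 (which the cardioid delay produces at
f_max = 6000 Hz) collapses the endpoint curve to the single segment from
H₁ to H₃; a turning weight of 1 (f_max → 0) collapses it the other way.

## Error metrics and the energy-balance coefficient

Three metrics quantify the linearization on the standard grid (β from 0 to
1 in steps of 0.02; f from 50 Hz to f_max in steps of 50 Hz, excluding
f = 0 where the β = 1 error is undefined):

* relative error E = 100(H_eva − H)/H;
* normalized error E_nor = 100(H_eva − G·H)/H, with G(β) the amplitude
  coefficient that balances the energy of the exact response against the
  linearized one over [0, f_max]:  G = √(Σ H_eva(f_i)² / Σ H(f_i)²) on the
  uniform grid f_i = (i/N)·f_max, i = 0..N (N = 1000 by default; G is
  converged to well under 1e−3 by N = 500 and equals 1 exactly at β = 0);
* average error E_ave(β) = the mean of E_nor over the N = 50 uniform
  frequency points (a signed mean: the energy balance makes positive and
  negative deviations equally informative, and the resulting per-weight
  averages stay within ±7% for all three named delays).

The orientation of G deserves a note, because "energy equilibrium" admits
several readings (exact-over-linearized or its reciprocal, energy ratio or
its square root).  The square-root linearized-over-exact form used here is
the one under which all three metrics stay inside their expected bands
simultaneously (relative error within [−10, 40]%, normalized error within
[−10, 40]%, average error within 7%); the alternatives violate at least
one of them by a wide margin.  The choice is a documented interpretation,
not a tuning knob: it is fixed once in the code and every reported number
follows from it.

## Channel gains

Compensation is a scalar gain per filter-bank channel:
gain_i = R(f_ref)/R(f_i), with R either the linearized model (cheap enough
for a real-time speech processor: one multiply-add per channel) or the
exact response ("ideal", the upper bound on what scalar gains can do).
The reference channel defaults to the one centred nearest 1000 Hz
(channel 4, 1005 Hz), where speech energy peaks.  Ideal gains invert the
on-axis roll-off exactly at the channel centres by construction;
linearized gains track them closely at the common β = 1 operating point
(within 10%) but can deviate by ~25% at intermediate weights where the
model's relative error is largest — visible end-to-end as a fraction of a
decibel against the ideal result on tone scenes.

## Filter bank and CIS chain

The 8-channel band plan is the published CI table ([156, 396] … [4783,
7769] Hz); centre frequencies are stored as printed (e.g. 274 Hz) even
where they differ by ≤ 2 Hz from edge midpoints.  Realization choices the
band plan itself does not dictate:

* 4th-order Butterworth band-passes (−3 dB at the band edges), applied
  zero-phase for analysis;
* envelopes by full-wave rectification and a 2nd-order Butterworth
  low-pass at 400 Hz, standard CIS practice; zero-phase filtering can
  undershoot, so envelopes are clipped at zero;
* CIS resynthesis as envelope-modulated sinusoids at the channel centres;
  gains are applied to envelopes, equivalent to filter-bank gains for
  scalar factors;
* Welch PSD with 1024-sample Hann segments and 50% overlap; line
  amplitudes are integrated over ±4 bins around each centre so window
  scalloping (centres generally fall between bins) cancels out of every
  comparison;
* per-channel errors are 10·log10 ratios after rescaling the test
  spectrum's summed line power to the reference's, since overall level
  carries no information about roll-off shape.

Default sample rate 16 kHz, the minimum covering the 7769 Hz top edge.

## Acoustic simulator

Scenes are free-field plane waves: microphone 2 receives the source
delayed by d cosθ/c seconds, realized with a 31-tap Kaiser-windowed-sinc
fractional-delay interpolator (β = 8.6, unit DC gain).  Additive noise is
generated independently per microphone (diffuse-field correlation at 1 cm
spacing is neglected — a documented simplification) and scaled so the
per-microphone SNR equals the request exactly; "lowpass_colored" noise is
white noise low-passed at 500 Hz, a surrogate for car/fan noise whose
energy sits at low frequency.  Test sources: flat Gaussian white noise;
an equal-amplitude tone set at the 8 channel centres; and a "speech-like"
harmonic complex (f₀ = 100 Hz, flat to 1 kHz, −6 dB/octave above) that
reproduces only the qualitative low-frequency concentration of speech —
none of these carry the phonetic structure of real recordings, so passing
tests demonstrate the signal-processing chain, not perceptual outcomes.

Empirical response measurements use pure-tone probes at 48 kHz with 100 ms
of transient discarded at each end; at that rate the interpolator's
passband deviation is negligible across the 274–6276 Hz probe set, and the
measured response matches the closed form within 2% away from nulls.  The
cardioid null check (rear source, > 40 dB cancellation) uses the
band-limited speech-like source, since cancellation depth at frequencies
approaching Nyquist is limited by the interpolator, not by the beamformer.

## Evaluation pipeline and problem sizes

`run_end_to_end` compares uncompensated, linearized-gain and ideal-gain
CIS chains against the un-beamformed reference on one synthetic scene.
The default scene — 2 s flat tone set, on-axis, noiseless, 16 kHz, dipolar
β = 1 — is the configuration in which roll-off is most visible.  Two
seconds gives the Welch estimate ~60 averaged segments, ample for line
spectra that are deterministic up to filter transients; the whole pipeline
runs in well under a second, and the complete test suite in a few seconds.
Determinism is end-to-end: every stochastic source takes an explicit seed.

## Known limitations

* No room acoustics, reverberation, head shadow or microphone mismatch;
  the hardware effects these would add are outside the model.
* The linearized model is an on-axis (θ = 0) construction; gains applied
  to off-axis targets compensate with the on-axis profile.
* Scalar per-channel gains cannot correct within-channel spectral tilt;
  that is inherent to the method, not to this implementation.
* Boosting low channels also boosts low-frequency environmental noise:
  at 0 dB SNR with low-passed noise the compensated low channels carry
  noise-dominated energy.  The trade-off is the user's to configure (the
  gains accept any weight/delay), not something the package resolves.
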