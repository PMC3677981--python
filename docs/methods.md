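# Methods

## Stimulus geometry

A condition is (motion type, shape, duration `T`, amplitude). The
acceleration phase occupies `[0, T/2]` and the deceleration phase is its
negated mirror image on `[T/2, T]`, so every profile ends at rest and the
acceleration trace is antisymmetric about `T/2`. Within the acceleration
phase the triangle rises linearly to its peak at `T/4`; the trapezoid
reaches peak at `T/10`, holds until `2T/5`, and falls to zero at `T/2`.
This is the unique reading of "trapezoidal/triangular, duration `T`" that
reproduces all eight published travel distances (total displacement
= peak velocity × `T/2` for both shapes). Rotation amplitudes are peak
angular velocities (the conventional unit, since canal afferents encode
velocity at mid frequencies); peak angular acceleration is derived
internally (`4v/T` triangle, `v/(0.4T)` trapezoid) and all model inputs are
acceleration traces. Units stay in m/s² and °/s² so the gain `K` carries
s²/m or s²/°. Default sampling is 1 kHz, the rate of the original IMU;
durations are assumed to sit on the sample grid (true for all built-in
conditions).

## Sensor dynamics and discretization

`H(s) = K(1+τ_N s)/((1+τ_1 s)(1+τ_2 s))` is simulated by exact
zero-order-hold discretization of the transfer function at the profile's
sample rate (`scipy.signal.cont2discrete` + `lfilter`), zero initial state.
The independent check is a dense-grid (10 kHz) convolution with the
analytic impulse response obtained by partial fractions
(`h(t) = A e^{-t/τ_1} + B e^{-t/τ_2}`, confluent closed form for a repeated
pole). The convolution uses trapezoid-rule end corrections: without them
the oracle itself carries O(dt) error for the translation parameter sets,
whose impulse response is spike-like (`τ_N ≫ τ_2`, `h(0) ≈ 1.7·10³`). With
the corrected oracle, ZOH at 1 kHz agrees to ≤ 0.24% of the response peak
for every built-in condition (first-order hold, also available, is exact
for these piecewise-linear inputs, ~10⁻⁵). Crossing detection uses
`|firing rate| ≥ 1` (direction-symmetric readout) with linear interpolation
between bracketing samples; halving the time step moves latencies by
< 0.3 ms. A stimulus that never crosses yields an explicit `None`, not an
exception, so condition sets can be filtered.

## Ex-Gaussian machinery

The density is evaluated in log space (`log_ndtr`) so it remains finite for
`τ ≪ σ`. ML fitting runs Nelder–Mead over `(μ, log σ, log τ)` from a
method-of-moments start (`τ₀ = sd·(skew/2)^{1/3}`, floored at 1% of sd).
Standard errors are the inverse *observed* information (numerical Hessian
on the natural scale at the optimum, via statsmodels); the *expected*
information (quadrature of score outer products) is used where only
parameter values, not raw samples, exist — e.g. reproducing the published
5 ms SD of the condition-I `μ̂` at n = 600 (computed: 5.11 ms). A fit whose
`τ̂ < 0.05 σ̂` is flagged as a near-degenerate exponential component. The
mode is the bounded argmax of the density on `[μ−3σ, μ+τ]`. The
likelihood-ratio test compares one pooled ex-Gaussian against separate fits
(3 extra df), with the conventional `D > 16.3` (`χ²₃` at 0.999) rule; fits
are always to data pooled across (simulated) participants — 30 trials per
participant are too few for stable individual fits.

Reproduction tolerances: published modes are recomputed to within 1.5 ms
rather than 1 ms because the printed `(μ, σ, τ)` are themselves rounded to
1 ms and `∂mode/∂μ ≈ 1`, so input rounding alone propagates ~±1.5 ms
(condition V: computed 740.9 vs printed 742). Published rotation thresholds
are reproduced to 5% (condition V: 1.65 vs printed 1.6): the printed values
are one-decimal roundings of predictions made with the original studies'
measured stimuli rather than ideal commanded profiles.

## Identification from RT differences

The objective is the sum of squared pairwise errors over the six unordered
condition pairs, minimized by Nelder–Mead over `log(K, τ_N, τ_1)` (`τ_2`
fixed), initialized at the threshold-study parameter set, iteration cap
2000, objective tolerance 1 (ms)². Candidate points at which any condition
fails to cross threshold, or that leave a physiological box
(`K ∈ [0.05, 50]`, `τ_N ∈ [10⁻⁴, 10]` s, `τ_1 ∈ [0.05, 60]` s), receive a
large penalty. `T_additional` is then the mean of `RT − T_threshold` over
the four conditions, and predicted RT is `T_threshold + T_additional`.

**Identifiability.** For stimuli much shorter than `τ_1` the early response
is ≈ `(K/τ_1)(v(t) + τ_N a(t))`, so the six RT differences constrain mainly
the mid-frequency gain `K/τ_1` and `τ_N`; the objective is nearly flat
along the ray `K, τ_1 → ∞` with `K/τ_1` fixed. Under realistic trial noise
(published per-condition `σ, τ`, n = 600, giving `se(μ̂) ≈ 4–12` ms) three
parameters overfit six noisy differences: the noisy optimum lies well below
the objective value at the generating point and drifts along the ridge.
Measured over 20 seeded synthetic datasets: the gain `K/τ_1` recovers to a
median 9.5% and predicted RTs to a median 5.3 ms MAE, while raw `K` and
`τ_1` individually do not recover and `T_additional` alone is biased by
tens of ms — the *sum* `T_threshold + T_additional` is identifiable, the
split is not. (The published identification shows the same ill-conditioning:
its μ-based and mode-based routes land at `K = 2.86, τ_1 = 3.65` versus
`K = 1.01, τ_1 = 1.04`.) With the noise switched off, recovery is exact
(SSE ~10⁻¹⁰, `T_additional` to < 10⁻³ ms).

**Commanded vs measured stimuli.** The published residual-latency constants
(287 ms rotations, 290 ms translations for the μ measure) derive from
*averaged IMU-measured* stimuli, never released, with the RT time base set
by a cross-correlation onset estimate. Driving the published RT-μ rotation
parameters with ideal commanded profiles yields `mean(μ − T_threshold)`
≈ 215 ms, and the pairwise errors of that parameter set on commanded
profiles reach −45 ms (SSE ≈ 8.8·10³ (ms)² vs the published 171): the
published parameter set is consistent only with the measured stimuli. A
soft actuator onset biases the cross-correlation onset late by a common δ,
which depresses the commanded-profile constant by exactly δ while leaving
pairwise differences intact. The acceptance surface therefore reports the
faithfully computed commanded-profile value and the discrepancy is left
visible rather than absorbed.

## Synthetic data

The generator emulates the stated experimental world: per condition, 600
correct trials (20 participants × 30), error trials injected at 4% and
excluded before fitting, RTs drawn as Gaussian + Exponential with the
published per-condition `(σ, τ)` and the location set so that the
distribution's `μ` (optionally its mode) equals `T_threshold +
T_additional`. Recordings are the commanded signal (acceleration for
translations, velocity for rotations — what the gyroscopes reported)
delayed by an onset lag, plus a deterministic vibration waveform, plus
seeded white noise at 1 kHz. The vibration default (three fixed-phase
sinusoids at 13/24/37 Hz, 12/8/5% of peak, translations only) is a
synthetic stand-in — the real spectrum was only ever shown graphically —
so green recording tests establish the *mechanics* (averaging suppresses
random but not deterministic components; cross-correlation recovers onsets)
and not the platform's actual vibration content. Single-trial onset
estimation is 1 ms-accurate at ≤ 2% noise; at 10% noise the smooth stimuli
give a broad correlation peak and several-ms jitter, restored to 1 ms by
the protocol's 40-repetition averaging.

## Numerical choices and limitations

* Simplex optimizers are deterministic; all stochastic steps take explicit
  seeds and datasets export byte-reproducibly.
* `sensory_threshold` stays at 1 and is never fitted; `K` absorbs the scale.
* Central processing is assumed not to reshape the transfer function; no
  afferent population heterogeneity, adaptation, or tilt–translation
  disambiguation is modeled.
* Translation-specific published constants (290/339 ms, SSE 612 (ms)²,
  translation thresholds) depend on the unpublished vibration-laden IMU
  traces and are reported for comparison only, never gated.
* No plotting: the report surface is CSV plus text summaries.
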