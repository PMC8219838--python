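# Methods

This note documents the models implemented in `lgnsnr`, the parameter
choices behind the shipped defaults, and what the synthetic data can
and cannot establish.

## Stimuli and the behavioral model

Stimuli are drifting Gabors specified in cone-contrast space. The L and
M cone contrasts are equal in magnitude, in phase for luminance (L+M)
and in counterphase for chromatic (L−M) modulations. The temporal
envelope is a trapezoid with 166 ms linear ramps on a 1 s presentation;
an empty `ramp` degenerates to a rectangle and `2·ramp = duration` to a
triangle, both valid. Contrast is fractional cone contrast throughout;
time is in seconds, frequency in Hz, visual angles in degrees.

Behavioral sensitivity per color direction follows the standard
psychophysical filter family

    sensitivity(f) = | ξ₁ (i2πf τ₁ + 1)^(−n₁) − ξ₂ (i2πf τ₂ + 1)^(−n₂) |

— a difference of cascaded exponential low-pass stages. Defaults
(luminance: ξ₁=40, τ₁=8 ms, n₁=3 minus ξ₂=35, τ₂=16 ms, n₂=3;
chromatic: pure cascade ξ₁=90, τ₁=20 ms, n₁=3) were chosen once so
that chromatic sensitivity dominates at 1 Hz, luminance at 20 Hz, and
the luminance function is bandpass with a peak near 10 Hz. Sensitivity
declines log-linearly with eccentricity (default slope 0.025 log₁₀
units/deg around 5°); the stimuli are defined over 2–14°. Threshold
contrast is `1/sensitivity`, clipped to the display gamut caps (0.19
for L−M, 0.86 for L+M) with an explicit `clipped` flag rather than an
error: a display cannot produce arbitrary cone contrasts, and under the
defaults only the 20 Hz L−M condition clips.

Percent correct in the 2AFC task converts to d′ by `pc = Φ(d′/√2)`
with no lapse or bias parameter. Under this convention d′ = 1.27 gives
pc = 0.8155, i.e. 82% at whole-percent rounding; the package treats the
pair as consistent at rounding precision only and does not force a
tighter identity.

## F1 d′ estimation

The per-trial response statistic is the magnitude of the complex F1
projection, `|Σ_k exp(−i2πf t_k)|` over spikes in the counting window.
Magnitude (rather than a signed projection onto a fixed phase) is used
because response phase is unknown a priori; this choice costs a small
bias (the blank-trial magnitude is Rayleigh-distributed, not
zero-mean) but needs no phase calibration. d′ uses the equal-weight
pooled-variance convention. Blank trials are rescored at each stimulus
condition's frequency, so one blank set serves all conditions. Negative
estimates are legitimate sampling noise and are never truncated. If
both sample variances vanish with unequal means, d′ is reported as a
signed-infinity sentinel with a `degenerate` flag.

Bootstrap standard errors resample trials with replacement,
independently within the stimulus and blank strata (default B = 2000,
always explicitly seeded). Because the estimator depends on trials only
through their |F1| values, resampling the precomputed statistics is the
exact trial bootstrap.

The counting-window sweep offsets the window start and end
independently over 0–200 ms (20 ms default step) relative to stimulus
on/offset. Infeasible cells (start ≥ end) are NaN, not errors. The
level-set at the behavioral criterion (default 1.27) is returned as a
boolean mask. Note that the d′ surface contains oscillatory structure
at the stimulus period (window length modulates the blank |F1|
statistics), so latency is best read from *translated* windows (equal
start/end offsets), where the optimum tracks effective response latency
(neuron latency plus kernel peak time).

The spike-triggered average is the spike-weighted mean stimulus at each
lag minus the raw stimulus mean; it is intended for receptive-field
localization and cell-type classification from white-noise runs, and is
undefined (an error) with zero spikes.

## Population pooling

Pooling N equally sensitive channels with pairwise noise correlation ρ
multiplies d′ by `k = √(N / (1 + (N−1)ρ))`: the √N law at ρ = 0,
saturating at 1/√ρ. The effective count weights neurons by the
*squared* local Gabor contrast (a neuron at the aperture fringe sees
reduced contrast and contributes reduced d′²), giving
`N_eff = density(ecc) · π σ²` for envelope SD σ. Defaults: magno
30/deg², parvo 132/deg² at 5° (4.4:1, parafoveal), log-linear decline
at 0.05 log₁₀/deg, ρ = 0.002 within class. With the 0.4° default
aperture this yields N_eff ≈ 15 (magno) and 66 (parvo) and a
parvo:magno scale-factor ratio of 2.0. Correlations between the two
cell classes are not modeled, so magno and parvo population d′ are
reported separately and never combined; each is a lower bound on the
joint population.

## Cone photocurrent model

Each cone's response is a linear kernel — a difference of unit-area
gamma filters, g₁·Γ(τ₁=8 ms, n₁=4) − g₂·Γ(τ₂=16 ms, n₂=6) with
g₂/g₁ = 0.25 — which is zero at t = 0, peaks near 25 ms, and
undershoots, matching the canonical biphasic photocurrent shape. Noise
is additive, stationary, Gaussian, independent across cones and of the
signal, with a one-sided PSD that is a sum of two Lorentzians
(corner frequencies 8 and 60 Hz). Noise traces are synthesized in the
frequency domain so the realized spectrum matches the configured PSD
exactly in expectation.

The matched filter is the optimal detector of a known signal in
Gaussian noise; folded onto positive frequencies against the one-sided
PSD its performance is `d′² = 4 ∫₀^∞ |S(f)|² / PSD(f) df` (the
equivalent two-sided form carries a factor 2; the Monte-Carlo
likelihood-ratio observer in the test suite pins the constant). Cones
are independent, so array d′² adds, and the Gaussian aperture weighting
collapses to the same `density · π σ²` effective count used for the
LGN population — the two stages are directly comparable by
construction. L and M cones see equal-magnitude contrast in both color
directions and contribute identically to the bound.

Kernel time constants can be scaled by a configured power of the ratio
of operating to calibration light level. The default exponent is 0 —
no extrapolation is applied — and the operating/calibration mismatch
(default 8000 vs 5000 photoisomerizations/s) is surfaced in the
pipeline's output metadata rather than silently corrected.

## Synthetic LGN

The stimulus is approximately uniform over a parafoveal receptive
field, so center and surround are purely temporal channels with scalar
cone weights sharing one gamma kernel; the surround is the center
kernel delayed by δ (default 10 ms). The firing rate is

    rate(t) = max(0, r₀ + g·[center](t−λ) − g·[surround](t−λ−δ))

with rectification at zero and inhomogeneous Poisson spiking (per-bin
counts at 1 ms, uniform placement within bins). Magnocellular defaults:
non-opponent center (w_L = w_M = 1) and a nearly balancing surround
(0.98 each, τ_c = 8 ms) — the delayed subtraction nulls slow L+M drive
and passes 5–10 Hz, and cancels L−M exactly. Parvocellular defaults:
single-cone center (L or M with equal probability per draw), mixed
surround (0.45 + 0.45, τ_c = 12 ms) — the surround drops out of the
L−M response, leaving the kernel's low-pass shape, and attenuates L+M.
Baseline rates (40/20 spikes s⁻¹), contrast gains (400/380 spikes s⁻¹
per unit drive) and latencies (90/110 ms) were calibrated once so that
population-level d′ at threshold contrasts spans roughly 0.5–7 — near
the behavioral criterion at 1 Hz and several-fold above it at 20 Hz —
and were not revisited afterward. Per-neuron draws jitter baseline,
gain (lognormal, σ = 0.15) and latency (σ = 0.05) while preserving the
weight structure that defines each class.

The generator omits, deliberately: explicit receptive-field spatial
structure, eye movements, spike-history effects (refractoriness,
bursting), and interneuronal noise correlations — correlation enters
only through the pooling formula. Passing tests therefore demonstrate
the estimators' correctness and the delayed-surround mechanism's
sufficiency for the tuning signatures, not fidelity to any particular
recorded neuron; in real recordings, correlated noise within a
recording session and non-Poisson variability would widen error bars
relative to the synthetic case.

## Pipeline

`run_experiment` derives every random stream from one master seed via
spawned `SeedSequence`s keyed by cell class, neuron, and condition:
identical config + seed gives byte-identical output tables. Stage
tables report, per condition, the behavioral criterion, per-class
population d′ with SEM-based standard errors (scaled by k), the cone
bound, and the cone→LGN difference and transmitted fraction. A
downstream d′ exceeding an upstream bound is physically impossible but
can arise from model error; it is reported as-is with an `unphysical`
flag and counted, never clamped. Gamut-clipped conditions are flagged
and logged.

Default problem sizes — 12 neurons per class, 100 trials per condition,
five frequencies per direction, 1 ms resolution — were chosen as a
desk-scale experiment that a laptop reruns in seconds while keeping
Monte-Carlo error in the per-condition population d′ below about 10%;
all are config-overridable.

## Known limitations

- The TCSF parameters are calibrated to the canonical ordering, not fit
  to any observer's trial data; absolute thresholds are illustrative.
- The F1-magnitude statistic is one of several defensible per-trial
  summaries (signed projection and two-dimensional discriminants are
  alternatives); the choice matters little for blank-referenced d′ but
  is not exposed as a config switch.
- Equicorrelated pooling with a single ρ per class is the simplest
  defensible correlation structure; spatially decaying correlations
  would lower k at large N_eff.
- The cone noise model excludes photon (Poisson) noise and any
  signal-dependence of the noise, appropriate at moderate photopic
  light levels only.
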