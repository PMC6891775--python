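# Methods

## The estimation problem

A driver's fatigue accumulates over a drive and is reflected in two
physiological channels: beat-to-beat heart-period variability and
spontaneous blink frequency. The time-domain HRV feature used here is the
variation coefficient of R-R intervals per aggregation window,
`RRVC = SDNN / M`, which is dimensionless and therefore comparable across
drivers with different resting heart rates. Fatigue is expressed relative
to two baselines: the seated-rest state before the drive (`RRVC_static`)
and the first driving window after the excitement period (`RRVC_initial`).
With `BDF = RRVC_initial − RRVC_static`, the driving fatigue degree is
`DFD_i = (RRVC_i − RRVC_initial) / BDF`; by construction `DFD = 0` at the
start of analysis, `FC_i − DFC_i = BDF` and `DFD_i · BDF = DFC_i` hold as
algebraic identities, and DFD is invariant under uniform rescaling of the
heart period.

On roads with rapid altitude change the heart rate responds to altitude
directly, so the HRV-based DFD is confounded exactly where monitoring
matters. Blink frequency is not confounded; its fatigue degree uses the
structurally identical normalization `(BF_i − BF_initial) /
(BF_initial − BF_static)`, forcing both curves through zero at the start,
which is the property that makes a multiplicative correction well-defined.
The correction is `rDFD_i = δ(h_i) · DFD_i` with `δ(h)` a cubic in
altitude, calibrated separately for upslope and downslope driving because
altitude moves the heart rate in opposite directions on climbs and
descents.

## Pipeline assumptions and numerical choices

- **R-R ingestion.** The primary input is an R-R interval series (field
  heart-rate belts emit intervals directly). ECG waveforms are supported
  through a Pan-Tompkins-style detector: 5–15 Hz band-pass (3rd-order
  Butterworth, zero-phase), squared derivative, 150-ms moving-window
  integration, a threshold at 30% of the 99th percentile of the integrated
  energy, a 0.3-s refractory period, and refinement of each candidate to
  the local maximum of the band-passed signal. The detector reports peak
  times on the sample grid.
- **Artifact removal.** Intervals outside 300–2000 ms, or differing from
  the previous retained interval by more than 20%, are dropped (both
  configurable); removals are counted, never imputed.
- **Excitement trim.** The first and last 1000 s of a drive are removed
  before any windowing; drivers' heart rates are unreliably elevated
  there. The initial baseline is taken *after* the trim (first post-trim
  window, `k` configurable).
- **Windowing.** Half-open windows `[start, end)`, default 120 s, tiled
  from the series origin; each beat belongs to exactly one window. SDNN
  uses the sample (n−1) estimator. Windows with fewer than 10 beats are
  excluded and enumerated. The window length is selectable from trend-fit
  diagnostics (regression F, significance-F) over candidate lengths
  {30, 60, 120, 180, 240, 300} s; two rules are implemented — prefer the
  120-s default among significant candidates, or take the minimum-F
  significant candidate — and the report flags when they disagree (on the
  shipped field table they genuinely do: 120 s vs 180 s).
- **Trend and breakpoints.** Cubic least squares in time via a
  centered/scaled basis (`numpy.polynomial` domain mapping), coefficients
  reported on the original scale; overall ANOVA F with (3, n−4) degrees
  of freedom. The fatigue-state breakpoint is the inflection
  `t* = −b2/(3 b3)`, reported only when `b3 ≠ 0` and `t*` lies inside the
  fitted span; a constant series yields zero slope coefficients and a
  flagged (NaN) F.
- **Slope classification.** The altitude profile is resampled at 1 s,
  smoothed by a 120-s moving average, and labeled by gradient sign against
  a flat threshold of 0.5 m per 120-s window; runs shorter than 300 s
  (transition bands around summits) merge into their longer neighbor, so
  segments partition the drive.
- **Calibration.** δ is estimated pointwise as `blink-DFD / HRV-DFD` per
  window; windows with `|HRV-DFD| ≤ 0.05` are excluded (near the
  zero-crossing the ratio is uninformative) and counted. The cubic fit in
  h requires ≥ 5 pairs spanning ≥ 200 m of altitude, otherwise it is
  rejected as ill-conditioned. Evaluation outside the calibration range
  warns. Upslope and downslope models are fitted on disjoint window sets.
  Flat segments use δ ≡ 1 unless a model is supplied — justified by the
  validity check below. Degree 3 is the default everywhere; it is a
  configuration option for sensitivity analysis.
- **Degeneracy guards.** The DFD denominator requires
  `|RRVC_initial − RRVC_static| > 1e-6` (same for the blink analogue);
  violations raise instead of returning infinities.
- **Agreement statistics.** Two fatigue curves are compared on their
  common window grid (nearest-time inner join, tolerance half a window —
  grids from different ingest paths are offset by fractions of a second)
  by the sum of squared differences and the simple-regression F,
  significance-F and R². The flat-segment validity check regresses
  pointwise δ on altitude over a low-variation segment; method consistency
  means *non*-rejection (significance ≥ 0.05) there.
- **Cohort averaging.** HRV parameters (M, SDNN) are averaged across
  drivers per window and RRVC recomputed from the averages; per-driver
  fatigue degrees are not averaged.

## Shipped reference models

`rdfd.reference` carries the field-calibrated artifacts for the
3540–4768 m Qinghai–Tibet route: the upslope and downslope correction
cubics (intercepts 366.711 and 493.703 at sea level — far outside their
calibration range, kept for exact model identification), the revised-DFD
time trends observed on that route (intercepts 8.658 and 4.436), and the
window-selection table. They are evaluation references; the raw field
recordings behind them are not distributable, so package tests validate
the *method* on synthetic data and the reference models by exact
evaluation.

## What the synthetic generator emulates

`rdfd.simulate` plants known ground truth so every stage is testable:

- an S-shaped (logistic) fatigue trajectory, midpoint 3000 s after the
  trim, plateau 8 in DFD units — the scale implied by the shipped revised
  trends; RRVC rises from 0.05 (initial) with a 0.03 static baseline;
- heart rate coupled to altitude piecewise-linearly (5 bpm per 1000 m,
  steepening to 15 bpm per 1000 m above a 4500-m knee — the altitude
  where the coupling visibly strengthens in field data; magnitudes are
  free parameters, not field claims);
- beat-by-beat intervals drawn truncated-Normal with mean `M(t)` and SD
  `SDNN(t)`, which realizes the RRVC parameterization directly;
- synthetic ECG as one Gaussian R-deflection per beat (with optional
  white noise at a chosen SNR and 0.25-Hz baseline wander), padded 0.5 s
  before the first beat so edge filtering cannot clip it;
- blink events as an inhomogeneous Poisson process by thinning;
- a *coupled* scenario in which the blink fatigue degree equals
  `δ*(h(t))` times the HRV fatigue degree exactly, with blink rates
  back-solved through the blink normalization (defaults BF_static = 14,
  BF_initial = 15 min⁻¹, chosen so back-solved drowsy rates stay below
  ~55 blinks/min while the blink curve can reach the δ·DFD range the
  field trends imply). Observation noise on the blink reference is
  *bounded* multiplicative (uniform within ±level); HRV estimation noise
  is represented at beat level, not duplicated on the window series.

What this does **not** emulate: realistic ECG morphology (P/T waves,
arrhythmia, electrode artifacts), eye-aperture signals (blink *events*
are the input), per-driver heterogeneity, or vehicle dynamics. Passing
tests therefore demonstrate correctness of the estimation machinery and
recoverability of planted physiology-scale structure — not detector
performance on clinical ECG, and not that field data meet the model's
assumptions.

## Problem sizes and determinism

Monte-Carlo checks use 200 seeds for recovery-rate and null-behavior
statements and 3–20 repetitions for the heavier end-to-end runs; synthetic
drives are 9000 s (58 windows) by default and 14000 s where a 100-window
calibration is wanted. All generators take explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seed reproduce
byte-identical outputs, and every pipeline output file embeds the
configuration hash and seed.

## Known limitations

- The pointwise-ratio construction of δ needs the HRV DFD to be bounded
  away from zero; early-drive windows are excluded, so δ is uncalibrated
  at the very start of a drive (where the correction matters least).
- The revision forces `rDFD = 0` wherever `DFD = 0`; the shipped revised
  field trends have nonzero intercepts because their time origin follows
  the excitement trim. Both the raw revised series and its fitted cubic
  are reported, without forcing a zero intercept.
- Calibration operates within a single trip; matching windows across
  outbound and return trips is not attempted.
- Window-length selection inherits a genuine ambiguity: a literal
  "smaller significance-F and F is better" rule picks 180 s on the
  shipped table while the preferred default is 120 s. Both results are
  always reported.
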