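# Methods

This note documents the models, estimators and numerical choices behind
`chronodelay`, and what the synthetic-data generator does and does not
emulate.

## Lighting protocols

Four housing protocols are built in, all on the Zeitgeber-time axis
(ZT0 = lights-on): `LD` (200 lx ZT0–12, dark ZT12–24), `DLE` (200 lx
ZT0–12, **20 lx ZT12–16**, dark ZT16–24), `LD16_8` (200 lx ZT0–16, dark
ZT16–24) and `DD` (constant darkness).  Schedules are per-day segment
lists and concatenate freely, so a protocol switch (e.g. 7 d LD then 13 d
DLE) is a first-class object.

## Activity generator

PIR counts per 10-s bin are Poisson around a two-state rate profile: an
active window of nominal duration α = 12 h starting at ZT12, and rest
elsewhere.  Defaults: `lambda_active` = 2.0 counts/bin, quiet-rest
`lambda_rest` = 0.13, masking factor 0.8 applied wherever the concurrent
lux is strictly between 0 and 200 (the dim evening).

**Marker-specific phase targets.**  A delaying protocol can move onset,
balance-midpoint and offset by different amounts, so each preset programs
three steady-state delays.  The window start carries the onset target, the
window length the onset−offset difference, and a two-level density step
inside the window places the activity-balance median at the midpoint
target.  A step (rather than a tilt) keeps both window edges sharp, which
the moving-average crossing rules need.

**Detector calibration.**  The short/long moving-average crossing rules
are biased when the window's duty cycle departs from 50% (≈ 0.3 h at DLE
geometry).  "Programmed delay" is therefore defined as *what the marker
rules recover on the noise-free rate*: the window geometry is
Newton-corrected (two iterations) against the actual detectors run on a
noiseless steady-state profile.  The stored ground-truth ψ trajectory
remains the programmed marker delays.

**Re-entrainment.**  After a protocol switch the phase state relaxes as
ψ_{d+1} = ψ_d + k(ψ_target − ψ_d) with k = 0.3/day (a ~1-week transition,
consistent with published actograms; no rate is reported, so k is a free
default).  Under DD the window drifts by τ − 24 h/day (default τ = 23.7 h)
from its last entrained phase; the prior-DLE preset carries a +4.0 h
initial phase.

**Sleep microstructure.**  Rest is fragmented by arousal bursts (Poisson
arrivals 0.5/h, exponential mean 24 min, rate 0.7 counts/bin) and the
active phase by naps (0.5/h, mean 18 min, quiet-rest rate).  With the
40-s immobility rule this yields light-phase sleep proportions ≈ 0.65–0.77
and dark-phase ≈ 0.1–0.2, matching published PIR sleep profiles, and it is
what makes short prior-sleep windows noisier proxies of 2-h sleep history
(the premise of the window scan).  The burst rate is kept below the daily
mean rate so arousals cannot cross the 24-h moving average and fake
onsets.  Mean rates are preserved exactly: the calibration profile uses
the arousal/nap-averaged rates.

**Presets** (steady-state onset/midpoint/offset delays, h): `wt_dle`
3.59/2.57/2.52; `opn4_dle` 2.74/2.32/1.61; `ld16_8` 5.80/3.56/3.16 (the
DLE values plus the reported additional long-day delays, so the two
presets contrast directly); `dd_prior_ld` and `dd_prior_dle` (τ = 23.7 h,
4.0 h group offset).

## Phase markers

The raw series is smoothed with a centred 1-h moving average; onset is the
first upward crossing of the 3-h over the 24-h moving average within each
ZT[6, 30) day window, offset the last downward crossing after the onset.
The midpoint is the upward sign change of (preceding 8-h activity −
subsequent 8-h activity).  Numerical choices:

- Moving averages are centred; even windows widen by one bin; positions
  whose full window does not fit are undefined, never zero-padded.
- Exact-zero runs of the difference: the crossing registers at the first
  subsequent nonzero bin of opposite sign.
- A day's markers are reported only when the difference series is defined
  across its whole ZT[6, 30) window — on edge days the "first crossing" is
  unidentifiable and would pick noise.
- Midpoint disambiguation: the first upward crossing *after the deepest
  negative excursion* in the day window.  The unsmoothed balance statistic
  wanders around zero from count noise while both 8-h windows cover rest;
  the pre-activity trough anchors the genuine crossing.
- Delays: per animal, mean marker over treatment days minus mean over
  baseline days on the unwrapped axis (successive daily values kept within
  ±12 h); group mean ± SEM.  Defaults: baseline = all LD days with valid
  markers, treatment = last 5 days with valid markers.
- Free-running period: τ = 24 + slope of unwrapped marker time on day
  index, requiring ≥ 4 valid days.  Group comparisons under DD use days
  observable in both groups (days 1–3 of a 5-day recording), since
  edge-day loss otherwise biases a drifting comparison.

## Sleep scoring

State 1 iff the bin lies in a maximal run of ≥ 4 zero-count bins;
proportion = sleep bins / total bins in a window; bout = maximal run of 1s
(≥ 40 s by construction).  In 4-h summaries the proportion uses per-bin
membership while a bout is assigned to the bin containing its onset — the
proportion stays exact and the duration interpretable.  Bout durations are
summarised as means (configurable).

## Bioluminescence and spectra

Background: linear interpolation between closed-shutter minutes (1 per
15), with linear extrapolation beyond the first/last closed minute, so
the correction is exact for piecewise-linear drift; corrected values at
closed minutes are interpolated from neighbouring open minutes.  Analysis
proceeds at 15-min resolution after block-averaging (stabilises Poisson
noise).

Band isolation uses the **stationary (undecimated) wavelet transform**
with `sym4`: the decimated transform's detail reconstructions are
shift-variant and displaced peak times by up to ~2.7 h in direct tests.
The circadian band is the dyadic 16–32 h level; the noise band for SNR is
0.5–4 h; SNR = variance ratio of the two reconstructions.  A linear trend
is removed before the transform (at circadian depths the filters span most
of a 5-day trace, so a residual trend's reflection kink leaks into the
band).

Acrophase φ = circular mean (mod 24 h) of per-cycle peak times of the
band signal (parabolic sub-sample refinement; peaks within 4 h of either
trace end are discarded as boundary artefacts).  Period τ̂ = 24 + slope of
unwrapped per-cycle acrophase on cycle index, dropping the first/last
cycle when ≥ 5 peaks are available (edge effects pull boundary peaks
inward).  Per-cycle peaks rather than a fixed-period cosinor, because a
free-running τ ≠ 24 h biases the latter.

The activity power spectrum is a complex-Morlet CWT at 6-min rebinned
resolution, power averaged over time with a one-period cone-of-influence
margin per period, and divided by scale so white noise is flat across the
period axis (bias-corrected spectrum).

## Expression rhythms

ΔCt = Ct(target) − mean(Ct of the two housekeeping genes), the exact
log-domain equivalent of dividing by their geometric mean (avoids
underflow); 2^−ΔΔCt divides by the highest cell mean within each lighting
condition, so per-condition maxima equal 1 exactly (and amplitudes are not
comparable across conditions — a property of the normalisation, recorded
here deliberately).  Acrophase: least-squares single-harmonic fit at fixed
24-h period via the cosine/sine linear parameterisation; the
centre-of-gravity (circular mean of ZT angles weighted by the positive
part of the rhythm) is reported from both the fitted wave and the raw
points, since the original CoG software's convention is not recoverable.
Fits with amplitude F-test p > 0.3 are flagged unreliable.  Δφ wraps into
(−12, 12]; pooling across tissues uses a two-tailed one-sample t test.
Sparse cells (n = 2–3) enter as-is; no imputation.

## Sleep–memory analysis

Recognition ratio = novel / (novel + familiar) exploration in the first
60 s of the test phase (later 60-s segments carried but not analysed by
default).  The window scan computes, for widths 10–180 min in 10-min
steps, each trial's prior-sleep proportion, averages ratio and sleep
within the 8 lighting × ZT × stimulus cells, and fits an OLS line across
the cell means; R²(t) is summarised by its quadratic trend and plateau
(R² at 120 min; smallest t with R² ≥ 0.95 of the maximum).  A per-case R²
across all 88 trials is reported alongside.

The mixed model is a random-intercept Gaussian LMM fitted by **maximum
likelihood** (not REML, for deviance comparability); the sleep effect is
tested by the 1-df likelihood-ratio χ² against the intercept-only model,
and its 95% CI comes from a parametric bootstrap (simulate from the
fitted model, refit, percentile interval; default 10,000 iterations, with
smaller counts used in the test suite for runtime).  Singular
random-effect fits fall back to ordinary regression with a flag.
Undefined ratios (zero exploration) are excluded listwise.

**Recognition generator.**  Each of 11 mice runs 8 trials (LD days 3–6,
DLE days 16–19, alternating ZT2/ZT14 and object/odour).  The ratio is
r = clamp(β₀ + β₁·S2h + b_i + ε, 0, 1) where S2h is the mouse's *true*
2-h prior-sleep proportion computed by the sleep scorer on its own
generated counts — so activity, sleep and memory are mutually consistent.
Exploration times are back-filled from r given log-normal segment totals
(median 20 s in the first minute); sample-phase exploration is drawn
independently of sleep, making the exploration analyses null by
construction.  The calibrated preset is β₀ = 0.45, β₁ = 0.37 (midpoint of
the reported bootstrap CI), σ_b = 0.05, and σ_e = 0.12 set once from a
noiseless calibration run so the expected cell-mean R² at the 2-h window
is ≈ 0.9.

## Problem sizes

Recovery checks use the study's own scales: 12 animals × 20 days for
entrained cohorts, 8 + 8 × 5 days under DD and for bioluminescence,
11 mice × 8 trials for memory, n = 4 replicates per qPCR cell.  The
type-I-error check of the LR test runs 200 simulated null cohorts; the
bootstrap-CI acceptance check uses 300 iterations, and the summary script
measures the 2-h R² as a mean over 3 replicate cohorts (the R² of an
8-point regression is itself a noisy statistic).

## What the generator does not emulate

No SCN or sleep-homeostasis dynamics (phase moves by a fixed geometric
relaxation); no melatonin, temperature or EEG; sleep is purely
immobility-defined, so REM/NREM structure and brief immobile wakefulness
are absent; count statistics are Poisson, without the burstiness of real
PIR electronics; light masking is a single multiplicative factor.  Passing
recovery tests therefore shows the *analysis chain* is correct and
well-calibrated at realistic effect sizes and noise levels — not that the
generator is a faithful physiological model.
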