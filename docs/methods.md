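# Methods

This note documents the models, numerical choices and known
limitations of the pipeline, in the order the data flow through it.

## Signal preprocessing

PPG cleaning follows mean correction → Savitzky–Golay detrending →
peak detection. The detrend subtracts a Savitzky–Golay smoother
(polyorder 3) from the signal; the window defaults to `4·fs + 1`
samples (~4 s). This window was chosen by measuring the smoother's
residual response: a ~2-s window places the ~1.25 Hz pulse band on a
negative side-lobe (residual pulse power ≈ 1.37× input) and wobbles
pulse maxima by several milliseconds, while the 4-s window preserves
pulse-band power within 10% and still removes sub-0.1 Hz drift
essentially completely.

Peak detection is a parameter-light local-maximum search: minimum
spacing 0.33 s (≤ 180 bpm), prominence ≥ 30% of the amplitude
inter-quartile range, computed after a light 20-ms Gaussian smoothing
that suppresses broadband noise maxima without shifting ~1 Hz pulse
peaks. Detected indices get a parabolic sub-sample refinement, which
removes the sample-grid quantization of peak times; on noiseless
synthetic pulse trains at 250 Hz the recovered RR intervals are within
~1.5 ms of truth (versus a one-sample bound of 4 ms).

Segmentation uses contiguous, non-overlapping 60-s windows; a partial
trailing window is discarded so all spectral estimates share equal
support. RR intervals are assigned to the window containing their
*terminal* peak, so each interval is counted exactly once. Whether
windows could overlap to enlarge the sample is left as a config knob
(`window_s`, stride via repeated calls); non-overlap is the default.

## Skin-conductance decomposition

The model is `SC = SC_tonic + SC_phasic` with
`SC_phasic = driver ⊛ k`, `k(t) = e^(−t/τ₂) − e^(−t/τ₁)` normalized to
unit peak, and `driver ≥ 0` sparse. Defaults τ = (1.0 s, 3.75 s) — the
canonical constants of the continuous-decomposition method — are
configurable.

The decomposition is a transparent two-stage procedure:

1. a coarse baseline: 5th-percentile levels on a 10-s grid joined by a
   monotone (PCHIP) spline, capped by the signal;
2. ridge-regularized non-negative deconvolution of the residual
   against the kernel (NNLS on the Toeplitz system augmented with
   √λ·I, λ = 1e−3), at a decimated working rate (25 Hz by default);
3. one refinement: the tonic level is re-splined through the
   *inter-impulse* sections only (windowed medians where the estimated
   phasic is < 2% of its maximum), followed by a final deconvolution.

The refinement matters: without it the baseline rides up inside SCR
windows and absorbs 10–25% of event amplitude; with it a unit synthetic
SCR is recovered with the driver impulse at the exact working-rate
sample and amplitude error ≈ 2%. The returned tonic is defined as
`smoothed SC − phasic`, which makes the conservation identity exact by
construction; the deconvolution misfit is reported separately as
`residual_rms`.

SCR events are phasic local maxima with amplitude (peak − preceding
trough) ≥ 0.01 µS, the conventional threshold. The onset is where the
rise actually starts (last pre-peak sample within 5% of the trough
level) rather than the flat floor; the decay endpoint is the following
trough, cut early once the signal recovers to within 5% of the
pre-event level — otherwise a lone event's "following trough" is the
end of the window and decay times become window-length artefacts.

Input smoothing uses a fixed Gaussian kernel (σ = 0.2 s, configurable)
— a reproducible stand-in for adaptive smoothers whose behaviour is
tool-specific.

## Features

Per 60-s window: 19 HRV, 9 GSR, 24 accelerometer features (six
statistics per axis including the per-sample resultant; the sixth
statistic completing mean/median/SD/min/max is the range).

Numerical conventions, chosen once:

* **RMSSD** uses the standard estimator `sqrt(Σdᵢ²/(N−1))` over the
  N−1 successive differences. A variant with the radical over the
  numerator only (`sqrt(Σdᵢ²)/(N−1)`) appears in some write-ups but is
  dimensionally inconsistent with typical RMSSD magnitudes; it is
  available behind `printed_rmssd=True`.
* Sample (n−1) variances throughout; kurtosis is non-excess
  (normal = 3); Poincaré `SD1 = SDSD/√2`,
  `SD2 = sqrt(2·SDRR² − SDSD²/2)` floored at 0.
* **Spectra**: the RR series is cubic-spline interpolated to a uniform
  4 Hz grid, linearly detrended, and a Hann-taper periodogram is
  integrated over VLF (0.003–0.04 Hz), LF (0.04–0.15), HF (0.15–0.4)
  and TP (0.003–0.4). A 60-s window cannot resolve VLF (lowest
  resolvable frequency ≈ 0.017 Hz); VLF is still emitted for
  completeness of the feature list but should not be interpreted.
  Ratios are NaN when the denominator band is empty.
* **Entropy** is Shannon entropy (base 2) of a 16-bin histogram of the
  window's SC values; **BandPower** integrates the phasic periodogram
  over (0, 1] Hz.
* The physiological feature block is 19 + 9 = 28 columns (52 with the
  accelerometer). Some accounts of this battery count 29 (and 53);
  no definition of a 29th feature is available, so the table emits
  28/52 and the discrepancy is documented rather than resolved.
  Config accepts `spectralEnergy`/`bandPower` as aliases of the same
  phasic-power feature when mapping external predictor lists.

Windows whose RR series is too short for the spectral estimate (fewer
than 8 intervals or < 30 s span) are dropped with a warning rather
than padded.

## Questionnaires

NASA-TLX: overall cognitive load is the unweighted mean of the six
subscales by default (RTLX convention); the pairwise-weighted variant
(Σwᵢrᵢ/15) is first-class. On this instrument a higher performance
rating means worse self-assessed performance, i.e. performance enters
the load score in the same direction as the other subscales; reversing
it (100 − rating) is a radar-chart display transform only and never
touches the score. Short DSSQ: each state (engagement, distress,
worry) is the sum of eight 0–4 items, bounded on [0, 32]; reverse-keyed
items are assumed pre-coded.

## Assembly precision

For each trial, all C(n,2) unordered pairwise Euclidean distances
between piece marker centers are compared with the reference layout;
the trial statistic is the sample SD of the signed deviations
(observed − reference), and the session score is the mean over trials.
All pairs (not only adjacent pieces) are used — this is parameter-free;
the pair set is configurable. Signed deviations preserve systematic
compression/expansion of the assembly; the statistic is invariant to
any rigid motion or reflection of the observed pattern, which the
generator's random rigid motion exercises explicitly. Units are
whatever the coordinate input uses (pixels by default); no metric
calibration is attempted.

## Statistics

Paired contrasts are gated by a Shapiro–Wilk test on the paired
differences at α = 0.05: normal-looking differences go to Student's
paired t (effect size: paired Cohen's d = mean(d)/SD(d)); otherwise
Wilcoxon signed-rank. The Wilcoxon implementation uses Pratt's zero
handling, mid-ranks for ties, no continuity correction, and an exact
null distribution of the positive rank sum (dynamic programming over
sign assignments, valid with ties) for n ≤ 25, with the
variance-corrected normal approximation beyond; the reported Z is
(W⁺ − µ)/σ and the effect size is the matched rank-biserial
correlation (W⁺ − W⁻)/(W⁺ + W⁻), which saturates at ±1 for one-sided
difference patterns. Comparisons are always first-listed minus
second-listed, so effects are negative when the second condition is
higher. Degenerate contrasts (zero-variance differences) are flagged,
not tested.

The repeated-measures ANOVA is one-way within-subject. Mauchly's W is
computed on the orthonormal-contrast covariance with the chi-square
approximation including the second-order Box correction term (matching
common implementations to ~4 decimals). When Mauchly rejects at
α = 0.05, the Huynh–Feldt epsilon multiplies both F degrees of freedom
(ε capped at 1 and floored at 1/(k−1); ε_HF ≥ ε_GG on every dataset by
construction). Post-hocs are simple pairwise paired t-tests with
Cohen's d and Holm adjustment by default (Bonferroni/none available) —
simple paired tests rather than pooled-error contrasts, consistent
with reporting paired effect sizes per pair.

## Classification

Features are z-scored, then fit by maximum-likelihood multinomial (or
binary) logistic regression via statsmodels, with the designated
reference class coded as outcome 0 so a negative coefficient lowers
the odds of a condition relative to the reference. Backward
elimination starts from the full candidate set and removes, per
iteration, the feature whose best (smallest-across-classes) Wald
p-value is largest, while it exceeds removal_alpha = 0.10; an
AIC-improvement criterion is available. Constant features are dropped
pre-fit. The likelihood-ratio statistic is 2(LL_model − LL_null) with
df = (classes − 1) × retained predictors — an identity asserted on
every fit.

Perfect separation or non-convergence triggers a flagged fallback: a
ridge-penalized multinomial fit (λ = 1e−4, intercepts unpenalized,
L-BFGS on the exact penalized likelihood), which stays finite under
separation; Wald p-values are reported as NaN there and elimination
treats such features as non-significant.

Metrics are accuracy and macro-averaged precision/recall, reported
in-sample by default (the battery's apparent convention) with
stratified k-fold — selection re-run inside each training fold — as
the honest companion; both are labelled and neither is claimed to
reproduce any particular observed cohort.

## The synthetic generator

The generator's defaults are the study conditions: 30 participants,
250 Hz sampling, a 3-minute baseline, a 5-minute session floor with a
minimum of three repetitions of each of the two assigned patterns, and
the four counterbalanced subgroups (order × pattern-set). A single
study seed spawns per-participant substreams (`SeedSequence.spawn`),
so identical (config, seed) yields identical studies and substreams
are parallel-safe.

Condition-dependent parameters, and where they come from:

* **Questionnaires** use the published descriptive statistics as
  generating means/SDs: cognitive load 39.84 ± 13.74 (visual) vs
  57.24 ± 14.71 (code); DSSQ means/SDs per administration (e.g.
  distress 9.00 → 6.56 → 11.83 across pre / post-visual / post-code).
  Scores are truncated normals within scale bounds, decomposed exactly
  into item responses; a person-level latent effect shared across
  sessions (SD 12 for TLX; 60% of the state SD for DSSQ) induces the
  within-subject correlation that paired tests rely on.
* **Performance**: per-repetition durations are lognormal with CV
  0.25 and means 33 s (visual) vs 80 s (code), chosen so the implied
  NTR (~9.8 vs ~6.4, code stuck at the minimum of 6) and TCT (~5.3 vs
  ~8.4 min) match the reported session means; repetitions alternate
  between the two assigned patterns and continue past the floor until
  each reaches three.
* **Placement noise**: isotropic per-piece SD 4.0 px (visual) vs
  3.0 px (code) — the code condition is slower but more precise —
  plus a random rigid motion (rotation uniform on [0, 2π), translation
  uniform in ±50 px) of the whole assembly, which carries no
  information and is a deliberate test lever for the precision
  statistic's invariance.
* **Physiology** (magnitudes not published; chosen once as
  field-realistic for seated light assembly): mean RR 850/800/760 ms
  and RR jitter 45/38/32 ms for baseline/visual/code (heart rate up,
  variability down with load), with 0.1 Hz and 0.25 Hz RR modulation
  whose amplitude shrinks with load; SCR rates 4/8/12 per minute with
  lognormal amplitudes around 0.3 µS and a slowly drifting tonic
  level (2.0/2.5/3.0 µS); one accelerometer burst per repetition
  (Hann-windowed ~4 Hz oscillation, ~0.5 g) over a 1 g gravity
  baseline with 0.02 g sensor noise.

The PPG pulse is an asymmetric Gaussian (rise σ 0.06 s, fall σ 0.12 s)
— only peak times matter downstream — with a DC offset, a slow trend
(sum of three sinusoids below 0.1 Hz) and white noise. The GSR forward
model is exactly the decomposition's model (tonic spline + driver ⊛
unit-peak Bateman kernel), so decomposition tests are true round
trips. Inter-repetition timing distributions are exposed as config
with the neutral lognormal defaults above.

What the generator does *not* emulate — and hence what passing tests
do not show about real data: realistic PPG morphology (dicrotic
notch), motion artefacts on the sensing hand, electrode drift or
contact losses, respiration-coupled HF structure, questionnaire
response styles, or marker-detection failures. Recovery results on
synthetic studies demonstrate the pipeline's correctness under its own
model assumptions, not field robustness.

## Problem sizes used in the test and acceptance runs

Signal-level unit tests run 60-s fixtures, mostly at 50 Hz with the
deconvolution at a 10–25 Hz working rate. Study-scale recovery runs
20 seeds of 30-participant studies in behavioural mode (signals
omitted; questionnaires, schedules and placements retain the full
generative structure), and requires the five qualitative condition
effects (cognitive load, distress, NTR, TCT, precision) to be
recovered in sign in ≥ 95% of seeds. Calibration uses 10,000 null
replicates for the gated paired test (nominal 0.05 ± 0.02) and 200
replicates for RM-ANOVA power (d = 0.8, n = 30, ≥ 80%). The end-to-end
classification battery in the acceptance script runs an
eight-participant study at 50 Hz, leaving ~120 one-minute windows —
these sizes are the package's own choices for desk-scale runs; all
effect parameters stay at the study-condition defaults.

## Known limitations

* The deconvolution's NNLS is dense; very long unsegmented recordings
  should be decomposed per window (the feature builder does this).
* VLF on 60-s windows is reported but unresolvable, as noted.
* The 28-vs-29 feature-count ambiguity is documented, not resolved.
* In-sample classification metrics on small studies are optimistic;
  use the k-fold scheme for honest generalization estimates.
* The Wilcoxon exact path enumerates the positive-rank-sum
  distribution; beyond n = 25 the normal approximation (with tie and
  zero corrections, no continuity correction) takes over.
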