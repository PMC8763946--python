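# Methods

This note documents the models, parameter choices and numerical conventions
of the pipeline, and what the synthetic cohort does and does not emulate.

## Synthetic cohort model

The generator produces, per subject, a continuous EEG recording and a pupil
diameter trace on a common 256 Hz clock, following the task design: each
trial is a fixation cross (uniform 900–1300 ms) followed by an 1100 ms
stimulus; trials are 7:3 Go:Nogo with equal 30°/150° rotation counts within
each type, randomised once per cohort (every subject sees the same order);
sessions are contiguous quarters of the trial sequence.  Two-minute
resting-fixation periods flank the experiment and 19 ten-second fixation
periods are evenly interleaved.  All trials are generated as correct
responses by default; an optional `error_rate` flags a random subset
incorrect (downstream analyses use correct trials only).

**EEG.**  Each trial emits a theta burst: a Hanning-windowed sinusoid at
`theta_freq` (5.5 Hz) over 0–1 s post-stimulus with a uniformly random phase
per trial (total, not evoked, power).  The source amplitude is
`theta_amp_by_session[s] × g_i × j_t` where `g_i` is a unit-mean log-normal
subject factor (σ = 0.35; keeps power positive and produces realistic
between-subject spread) and `j_t` a mild trial jitter (σ = 0.10).  Default
session amplitudes decline 20% from S1 to S4 (60 → 48 nA·m; around 60 nA·m
a burst projects to a few µV at the scalp, which is the realistic scale for
frontal theta).  Sources are two superior-frontal grid dipoles (±2, 3,
5.5 cm in right/anterior/superior head coordinates) with a fixed oblique
orientation, forward-projected through the head model below.  Background
activity is channel-independent 1/f-power noise whose theta-band RMS is set
so that the *nominal* session-1 burst yields a theta SNR of
`background_snr` (default 5).  The reference level is deliberately constant
across subjects and sessions — tying it to each subject's own burst power
would cancel the programmed effects after baseline normalisation.  White
sensor noise (default 2 µV SD) supplies the broadband floor a real
amplifier shows; without it the smooth 1/f background can sit below the
0.5 µV/100 ms dead-channel rejection criterion.

**Pupil.**  The trace is a tonic baseline (3.62 mm, drifting upward at
0.065 mm/h — reproducing a ~0.17 mm rise over a 2.7 h session) plus a
per-trial phasic response: an Erlang-family kernel
`h(t) = (t/t_p)^k e^{k(1 − t/t_p)}` with peak latency `t_p = 1.2 s` and
shape `k = 10.1` (the standard pupillometry response family, parameterised
by its peak so tests can move it), scaled per trial.  150°-rotated trials
get ~1.19× the 30° amplitude (working-memory load effect, from the printed
condition means 0.068 vs 0.057 mm).  Per-subject session amplitudes are
constructed as `μ_s (1 + cv·(ρ_s z_i + √(1−ρ_s²) ε_i))` where `z_i` is the
standardised ground-truth **log** theta power of subject *i* in session *s*
— this makes the across-subject theta–pupil correlation equal `ρ_s`
(`coupling_by_session`, default −0.65 → 0 across sessions) by construction,
up to sampling noise.  The log scale is deliberate: the subject gains are
log-normal, so raw power is strongly right-skewed and a Pearson target
defined on it would be dominated by outlier subjects, and the analysis
correlates dB (log-scale) theta, so the programmed coupling lives on the
scale the method measures.  Session means default to 0.070 → 0.052 mm (printed
S1/S4 peak values); `cv = 0.30`; measurement noise 0.01 mm SD.

**What the generator does not emulate**: ocular/muscle artifacts (the
automated rejection criteria are exercised by crafted test epochs instead),
volume-conducted background correlations between channels, realistic head
geometry, behavioural reaction times, luminance effects on the pupil, and
blink dynamics (blink gaps can be injected via the mask but are not
generated).  Passing recovery tests therefore demonstrates that the
*analysis chain* is correct and calibrated, not that it is robust to every
artifact class of real recordings.

## Head model and leadfield

Three concentric spheres (brain/skull/scalp radii 8.7/9.2/10 cm,
conductivities 0.33/0.0042/0.33 S/m) with the exact per-degree series
solution: in each shell the degree-*n* potential is `A r^n + B r^-(n+1)`;
continuity of potential and radial current at the interfaces plus the
insulating outer boundary give a 5×5 linear system per degree (radii
normalised to the scalp radius for conditioning; series truncated at degree
60, converged to < 1e-8 for the deepest sources used).  With equal
conductivities the solver reproduces the homogeneous-sphere closed form
`(2n+1)/n` exactly, and it agrees with mne's Berg–Scherg sphere model to
< 2% in amplitude (test-verified).  Leadfields are average-referenced and
computed on a regular grid (1 cm default) strictly inside the brain shell.
An analytic sphere model was chosen over a realistic template head so the
forward solution is closed-form and independently checkable.

## Sensor analysis

Filtering uses 4th-order Butterworth sections applied forward-backward
(zero phase), giving the stated 48 dB/oct roll-off; the notch is a 2 Hz-wide
band-stop at 50 Hz; an additional 20 Hz low-pass precedes segmentation.
Artifact criteria are evaluated in a ±200 ms window around the stimulus and
*flag* epochs rather than deleting them.  The CSD transform is the
spherical-spline surface Laplacian (spline order m = 4, λ = 1e-5, Legendre
series to degree 50 — common published defaults; the source does not state
values) in µV/cm² on a 10 cm sphere; it requires ≥ 32 channels, so the
scaled 16-channel harnesses analyse plain potentials.

Morlet decomposition uses c = 5 cycles at every frequency (σ_t = 5/(2πf)),
a balance of time/frequency resolution in the theta band; the wavelet is
unit-energy under `A = (σ_t√π)^(−1/2)` and the discrete convolution is
scaled by the sample period so power is sampling-rate independent.
Frequencies: 4–7 Hz in 1 Hz steps for statistics (2–20 Hz available for
plots).  dB conversion is `10·log10(P/mean P over −200–0 ms)`, applied to
trial-averaged total power.

The cluster permutation test thresholds paired t-values at the two-sided
α = 0.05 critical value, clusters suprathreshold bins under channel
neighbourhood (arc distance ≤ 0.4 rad by default; the equidistant montage's
neighbourhood is not specified anywhere, this gives median degree ≈ 6 at 60
channels) × consecutive-time adjacency, sums t per cluster, and compares
|summed t| against the Monte-Carlo maximum-statistic null from random
within-subject sign flips (500 draws; p = (1+#exceedances)/(n+1)).  An
exhaustive mode enumerates all 2^n sign patterns and anchors the
Monte-Carlo path in tests.

## Source analysis

Theta CSD matrices are multitaper (Slepian) estimates over −750–0 ms (pre)
and 250–1000 ms (post), ±1.5 Hz smoothing around the 4–7 Hz band, averaged
over trials, tapers and in-band Fourier bins.  The DICS filter is built
from the pooled pre+post CSD of both compared sessions ("common filter"),
with diagonal loading `0.05 × trace(C)/N` (the standard reading of "5%
regularisation") and scalar orientation along the dominant eigenvector of
the per-voxel 3×3 source CSD (sign fixed by the largest component; the
orientation convention is not stated in the source and must be pinned for
reproducibility).  Session contrast: each session's post-stimulus power is
normalised by its own pre-stimulus power, `R_s = P_post/P_pre`, and
`P_diff = (R₄−R₁)/(R₄+R₁)`; a `eq2_literal` flag reproduces the
printed-form variant in which both ratios share the S4 pre-stimulus
denominator (where pre-stimulus power cancels algebraically).  Top-1% |P_diff|
voxels (ties broken toward the lowest index) are grouped into
grid-contiguous clusters and labelled from a small built-in ROI box table
(SMA, superior frontal, precentral, other) in grid coordinates — a
deliberate replacement for atlas lookup.  LCMV uses the broadband
covariance averaged over single-trial covariances (an `evoked` option uses
the covariance of the trial average; the wording is ambiguous and the
single-trial reading is the default), the same regularisation and
orientation conventions, unit gain at each ROI voxel; trial-wise source
series are averaged over ROI voxels before Morlet theta power, frequency
averaging and dB baselining.

## Pupillometry and coupling

Pupil conditioning: linear interpolation over blink-masked gaps, zero-phase
4th-order 20 Hz low-pass.  Epochs mirror the EEG (−0.2 to +3 s, −200–0 ms
baseline).  The phasic peak is the largest *interior* local maximum of the
per-subject average in 0–3 s with a 0.005 mm prominence floor (a peak-picking
rule is required but unstated; monotone averages yield missing values, never
endpoint maxima).  Tonic diameter is the raw (uncorrected) mean per fixation
period.

The coupling statistic correlates per-subject ROI theta power (dB, 0–1 s)
with per-subject average phasic pupil traces (0–2 s) across subjects —
never within subject trial-by-trial (single-trial EEG SNR is too low).
Cells with two-sided p ≤ 0.05 (uncorrected — masking, not inference) are
kept; significant negative cells are grouped by 4-connectivity (the
conservative choice; the blobs in question are contiguous under it);
components whose *centroid* lies in the theta 0–1 s × pupil 1–2 s window
are retained (an any-overlap rule is available); sizes are bin counts
(areas in s² are emitted alongside) normalised so the largest cluster
across the compared set is exactly 1.  Both time axes can be decimated
(default 8 samples ≈ 31 ms bins in the pipeline wrapper) — Pearson r on
bin averages — for tractable matrix sizes.

## Statistics

The 2×4 within-subject ANOVA uses the cell-means SS decomposition, each
effect tested against its effect × subject interaction.  Greenhouse–Geisser
epsilon is computed per effect from the covariance of orthonormal
(Helmert) effect contrasts, ε = tr(Σ)²/(df·ΣΣ²); for a 2-level factor
ε = 1 exactly.  Effect size is partial η² (consistent with the η² values
reported for within designs).  Implementation agrees with a loop-based
brute-force oracle to 1e-8 and with pingouin to 1e-6 (both test-enforced).
Post-hoc family sizes: Bonferroni m = 6 for session pairwise comparisons;
interaction post-hocs default to uncorrected paired t per angle.  Note the
GG correction is only guaranteed conservative for clearly non-null effects;
near F = 1 corrected and uncorrected p can cross.

## Problem sizes and calibration checks

The recovery and calibration harnesses run at reduced sizes, chosen as the
smallest scales at which the programmed effects are identifiable: 16-channel
montage, 40 trials/session, two sessions, n = 27 subjects for end-to-end
recovery (50 cohorts); 8 subjects for the 200-cohort null calibrations;
single-subject, 10-trial runs on the 1 cm grid for the 40 localisation
runs.  The cluster-test null calibration uses smooth Gaussian sensor maps
(squared-exponential spatial covariance, AR(1) time) as the map-level null
of the generator's background, since the test's family-wise error depends
only on the exchangeability of the two condition labels.  Fixation-period
lengths are shortened in the harnesses (they only pad the timeline); the
tonic-drift round-trip test keeps them.

## Known limitations

* The spherical head model localises well on its own grid but carries no
  anatomical realism; ROI labels are coarse boxes, not an atlas.
* The coupling statistic's per-cell p-values are uncorrected by design;
  its inferential weight comes from the normalised cluster-size comparison,
  not from the mask.
* Measured coupling is attenuated relative to the programmed ρ (regression
  dilution from finite-trial theta estimates); the recovery criteria are
  therefore ordinal (S1 vs S4), not calibrated to |ρ|.
* `eq2_literal` changes the contrast's sensitivity to pre-stimulus drift;
  the default per-session normalisation is the physiologically motivated
  reading.
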