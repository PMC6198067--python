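# Methods

This note documents the models, numerical choices and limitations of the
package; it complements the API docstrings.

## Physiological noise model

BOLD fluctuations synchronized with the cardiac and respiratory cycles
are modelled, per slice, by a 13-column nuisance set:

* **Cardiac phase** φc(t): piecewise linear from 0 at one pulse peak to
  2π at the next. Pulse peaks come from the PPG channel: the trace is
  band-passed (0.4–8 Hz, zero-phase Butterworth), and peaks are taken
  above an adaptive threshold (30% of the 95th amplitude percentile)
  with a 0.3 s refractory period. Evaluation times slightly before the
  first or after the last peak reuse the nearest inter-beat interval.
* **Respiratory phase** φr(t): π times the empirical CDF of the
  respiration amplitude (100 histogram bins, configurable), signed by
  the smoothed derivative of the respiration trace. This histogram
  equalization makes the phase invariant to amplitude scaling; a full
  inhale maps to |φ| = π and the mean amplitude to ≈ π/2.
* **RETROICOR basis**: cos(mφ), sin(mφ) for m = 1, 2 of both phases — 8
  columns bounded in [−1, 1].
* **RVT**: per breath, (peak − preceding trough) / local period, with
  the local period a centred peak-to-peak difference; breath-resolved
  values are linearly interpolated to arbitrary times with edge-value
  extension. Five columns: lags 0, 5, 10, 15, 20 s. Lagged evaluation
  before the start of the breath record holds the edge value — the 20 s
  lag is otherwise undefined for the first ten volumes.

All columns are evaluated at each slice's acquisition times
t_k = k·TR + slice offset. Correction projects every voxel's series onto
[intercept | its slice's 13 columns] and keeps the residual plus the
voxel temporal mean, so tSNR before/after remains comparable. The
projection can only reduce temporal variance; collinear columns are
dropped with a warning rather than failing. Correction runs on raw,
unsmoothed data, before any statistical modelling; motion parameters are
not part of this stage (they enter the GLM only).

## tSNR

tSNR = temporal mean / temporal SD with the sample (n−1) SD — the
difference from the population SD is immaterial at 216 volumes but is
fixed for reproducibility. Zero-SD voxels are flagged undefined, never
silently zero. Comparisons of corrected vs uncorrected data use
unsmoothed series; the fully processed series (including smoothing) can
be summarized separately.

## Event-related autonomic responses

Responses are epoched at stimulus onset over [0, 10] s against the mean
of the 1 s pre-onset baseline. Pupil curves are ratios to baseline —
unit-free, so any rescaling of the raw diameter leaves every derived
quantity unchanged; skin conductance is baseline-subtracted in µS. The
area under the deflection curve is computed two ways: trapezoidal with
physical units (%·s for pupil, µS·s for SC) as the primary measure, and
a plain sum over samples for comparability with percent-times-samples
conventions; which one downstream code consumes is explicit. Trials
lacking a full baseline or window are excluded with a logged reason, and
included + excluded counts always reconcile with the design.

Pupil recordings are cleaned by linear interpolation across invalid
runs, then a centred moving average over 100 samples with edge
truncation (a shrinking window, so constants pass through unchanged).
A recording whose *raw* invalid fraction reaches 10% is flagged rejected
— the strict reading of "fewer than 10% analyzed" — and the fraction is
counted before interpolation and smoothing. Skin conductance is median
filtered over 150 samples then averaged over 250, mirroring the
acquisition chain. Condition comparisons use a paired t on per-subject
condition means (df = n−1), habituation standardizes per-trial AUC to
the first trial and correlates the ratios with trial number, and the
percent Stroop effect is 100·(IC − CC)/CC.

## Task GLMs

The canonical HRF is a double gamma (peak gamma shape 6, undershoot
shape 16 weighted 1/6, unit scales), normalized to peak 1; it is 0 at
t = 0, peaks near 5 s and undershoots around 15 s. Stimuli are modelled
as impulses at onset by default — the regressor is the exact analytic
sum of shifted HRFs, which keeps noiseless recovery tests sharp — with a
boxcar option integrating the HRF over the 1.5 s presentation. Models 2
and 3 retain the unmodulated condition regressors and add one modulated
regressor per condition, the stimulus train weighted by the per-trial
covariate mean-centered *within condition*; centering makes the
modulated and unmodulated trains exactly orthogonal before convolution.
Drift is absorbed by a discrete-cosine set with periods above 128 s
(k = 1..⌊2·N·TR/128⌋, i.e. 6 functions at 216 × 2.04 s); motion and an
intercept complete the design.

Serial correlation is handled by a single pooled AR(1) coefficient.
Because the design projection (drift columns especially) absorbs part of
the serial correlation, the naive lag-1 autocorrelation of OLS residuals
is biased low; the estimator therefore iterates — whiten with the
current ρ, measure the remaining lag-1 correlation, subtract the
analytic projection bias trace(S·M)/trace(M) (S the symmetrized lag-1
shift, M the residual projector), and accumulate until the step falls
below 1e−4. On simulated AR(1) noise at ρ = 0.4 with 216 volumes this
recovers ρ to within ±0.01 on average. Per-voxel ρ is deliberately not
fitted: at ~200 samples per voxel the pooled estimate is far more
stable.

Second-level inference on the interference contrast is the voxel-wise
paired t across subjects (the two-condition within-subject factor is
equivalent to a paired test, df = n−1). Cluster inference thresholds at
the one-sided t critical value for voxel p < 0.005, labels
supra-threshold voxels with 26-connectivity, and drops clusters below an
extent k; k may be fixed or estimated as the expected supra-threshold
cluster size under seeded sign-flip permutations of the subject
difference maps (default 1000 flips) — an assumption-light stand-in for
parametric expected-cluster-size formulas. Smoothing is a separable
Gaussian with σ = FWHM/(2√(2 ln 2)) per axis converted to voxels from
the header (4 mm FWHM default). Atlas overlap reports the count and
fraction of cluster voxels inside an anatomical mask, resampling the
mask by nearest neighbour through the affines when grids differ.

## Synthetic sessions

The generator emulates the acquisition this package targets: 220 volumes
at TR = 2.04 s (first four discarded downstream, leaving 216), 18 + 18
stimuli of 1.5 s at a 10.5 s inter-stimulus interval with Gaussian onset
jitter (SD 0.5 s by default — the jitter distribution is a free
parameter, since only its existence is specified by the protocol), PPG
beats as Gaussian pulse bumps with jittered inter-beat intervals (65 bpm,
SD 30 ms), respiration as a sinusoid (15 breaths/min) with slow
amplitude modulation, skin conductance as a tonic level plus
bi-exponential SCRs (rise τ 0.75 s, decay τ 2 s, latency 1.5 s — the
canonical SCR shape; all constants configurable), and pupil dilations
with the gamma-shaped impulse response peaking at 0.93 s used in the
pupillometry literature, amplitudes 13.5% (CC) and 15.9% (IC) of
baseline. Blinks arrive as a Poisson process (10/min × 0.2 s ≈ 3%
invalid samples, matching typical usable recordings).

BOLD contamination is built from the *same* phase and RVT constructions
as the corrector, with per-voxel random Fourier/RVT coefficients, so it
lies in the correction span by design — a session with no thermal noise
quantifies removal exactly. Contamination is slice-locked (evaluated at
each slice's acquisition time); the task response is sampled at volume
onsets for every slice, matching data whose slice timing has been
harmonized before the GLM, which keeps the noiseless GLM recovery an
exact linear identity. Default gains (8/8/4 signal units on a baseline
of 1000, thermal SD 15) put the phase-locked variance on the order of
the thermal variance, which reproduces the regime where correction
roughly doubles tSNR in contaminated tissue. The grid defaults to
20×20×20 voxels of 1.4 mm so a session generates in about a second;
acquisition timing is unaffected by grid size. Motion parameters are
smooth low-amplitude random walks used as covariates only — no motion is
applied to the image, since realignment is out of scope.

What the generator does **not** emulate: susceptibility artifacts and
signal dropout, spatially correlated noise, realistic vascular
geography (contamination coefficients are i.i.d. across voxels), eye
foreshortening and gaze effects on pupil size, tonic/phasic SCR overlap
beyond kernel superposition, and any MR physics. Passing tests therefore
demonstrate the correctness of the algorithms under the stated model,
not robustness to every property of real recordings.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale configurations: full
sessions at the 20³ default grid, a 10-seed tSNR suite at 10³ with 150
volumes, GLM calibration on 10,000 simulated null voxels, and 20-seed
AR(1) recovery at 300 voxels — sizes chosen so the whole suite completes
in well under a minute per file while keeping Monte-Carlo standard
errors small. Every random draw descends from an explicit seed
(sub-streams are derived per component), and a regenerated or rerun
session/pipeline is byte-identical on disk.

## Known limitations

* Single-echo, single-run sessions only; no CompCor/ICA denoising, no
  heart-rate-variability convolution regressors.
* PPG-based beat detection only (no ECG); pupil validity flags are taken
  as given rather than re-detected.
* The slice→voxel mapping defaults to the last (slowest-varying) axis;
  acquisitions with a different slice axis must set `slice_axis`.
* Cluster extent estimation by sign-flip permutation assumes symmetric
  subject-level errors under the null.
* The pooled-ρ AR(1) model whitens all voxels identically; strongly
  heterogeneous autocorrelation (e.g. near large vessels) is averaged
  over.
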