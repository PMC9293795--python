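# Methods

This note documents the models, parameter choices, numerical decisions and
limitations of `alphalat`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted beyond what the
code measures.

## The analysis model

The pipeline estimates cue-dependent lateralization of posterior alpha
oscillations during the cue–target interval of a covert spatial-cueing
task, and its modulation by a stress manipulation indexed by salivary
cortisol.

**Preprocessing** (fixed order): 1–30 Hz zero-phase FIR band-pass →
bad-channel removal (robust z > 5 on channel kurtosis or log-variance) →
common average reference → downsampling to 200 Hz → cue-locked epochs
−1500…4000 ms → amplitude-threshold artifact rejection (|x| > 100 µV on
any retained channel) → a strict minimum-trial gate (a session with fewer
than 100 valid trials excludes the subject from all analyses; 100 exactly
is kept). Classifier-based artifact removal (ICA with an external trained
component labeler) is deliberately not part of the pipeline; the amplitude
criterion is a transparent, configurable stand-in, which is appropriate
here because the synthetic data's artifact structure is controlled by the
generator.

**Time–frequency decomposition**: 50 complex Morlet wavelets, center
frequencies linearly spaced 2–20 Hz, Gaussian tapers with temporal FWHM
scheduled linearly from 400 ms (at 2 Hz) to 100 ms (at 20 Hz); power is
the squared magnitude of the convolution, and epochs are pruned to
−500…3200 ms so that no retained sample's convolution window (kernel
support ±4σ ≤ ±680 ms) reaches beyond the epoch.

*Kernel normalization.* Kernels are normalized to unit gain at their
center frequency (the Gaussian taper sums to 1) rather than to unit
energy. Unit-energy normalization gives shorter (higher-frequency)
kernels a lower center-frequency gain (∝ √σ_t), which biases the
spectral argmax of a pure tone downward by up to ~1.5 grid steps across
this family; unit center gain makes peak-frequency diagnostics unbiased.
The lateralization index is a ratio of powers at a fixed frequency and is
invariant to any per-frequency scaling, so this choice affects only
diagnostics.

Note that the Gaussian Fourier pair of the 400→100 ms temporal FWHM
schedule implies a frequency-domain FWHM of 4·ln2/(π·FWHM_t) ≈ 2.21→8.83
Hz; the temporal widths are treated as the defining contract.

**Lateralization index**: per electrode pair (P7/P8, P3/P4, CP5/CP6) and
trial, channels are labeled contralateral/ipsilateral to the cued
hemifield; power is averaged over trials *first* and
LI = (pow_ipsi − pow_contra)/(pow_contra + pow_ipsi) is taken of the
averages (a regression test pins this order — the mean of per-trial LIs
is a different, noisier quantity). Pair LI maps are averaged over pairs
and smoothed along time with a 50-frame (250 ms at 200 Hz) centered
moving average with truncated (shrinking) edge windows before any
statistic. Bin summaries use half-open bins [0, 800), [800, 1600),
[1600, 2400) ms — a frame at exactly 800 ms belongs to the second bin —
and an alpha band of 8–14 Hz. The band is a configurable convention, not
an estimate.

**Cluster-based permutation inference.** Pointwise statistics are
thresholded at a two-sided pointwise p < 0.05 (critical t at the
subject-level df, or its r-transform for correlation maps); suprathreshold
points are grouped by 4-connectivity (time and frequency neighbors, no
diagonals — the conservative reading of "neighboring"), positive and
negative excursions separately; the cluster mass is the summed statistic;
each observed mass is referred to the null distribution of the maximum
absolute cluster mass over 1000 permutation iterations, with the add-one
estimator p = (1 + #{null ≥ obs})/(1 + n_perm), whose floor is exactly
1/(n_perm + 1).

Three null constructions:

* *Cue test.* Each subject receives a fixed surrogate LI built by swapping
  the contralateral/ipsilateral assignment independently per trial
  (p = 0.5). The observed map is the one-sample t over subjects of
  (LI_observed − LI_surrogate); each null iteration replaces LI_observed
  by a freshly re-shuffled LI against the same surrogate. Swapping leaves
  the contra+ipsi power sum invariant, so every re-shuffled LI is a linear
  function of the swap indicators — the whole permutation pass reduces to
  one matrix product per subject. (The alternative reading, redrawing the
  *surrogate* each iteration while keeping LI_observed, makes observed and
  null rows identically distributed even under a true effect and was
  rejected for having no power.)
* *Condition test.* Paired t of (stress − control) subject maps; null
  flips each subject's condition label independently. An `exact=True` mode
  enumerates all 2^n sign patterns for small n and is checked against
  brute-force enumeration.
* *Coupling test.* Pointwise Pearson r between per-subject ΔLI maps and
  ΔAUCi; clusters are formed on r thresholded via its t-transform
  (df = n − 2) with summed r as mass; the null permutes ΔAUCi across
  subjects.

The Fisher-Z window contrast averages atanh(r) within the alpha band
inside the 870–1535 ms window and over the remainder of the cue–target
interval, separately per channel pair, and compares them with a dependent
one-sided t-test across the three pairs (df = 2). Points with |r| = 1 are
flagged and excluded. With only three pairs this test has coarse
resolution (one-sided p can only be small if all three pairs agree); it is
a specificity check, not a primary inference.

**Cortisol.** AUCi is the trapezoidal area under the concentration–time
curve minus baseline × duration, baseline = the first (−10 min) sample;
all seven samples (−10, 0, 15, 20, 35, 50, 65 min) enter. ΔAUCi is
stress − control per subject; subjects missing a session are excluded and
logged.

## The synthetic-data generators

**Full EEG generator** (`synth.generate_study` / `iter_sessions`).
20 subjects × 2 sessions (stress/control, order counterbalanced), 288
trials per session (one third tagged as catch trials with identical
cue-locked structure), 32 channels at 1000 Hz, cues balanced L/R. Each
trial is 1/f noise (exponent 1.0, 6 µV) plus an alpha sinusoid at the
subject's alpha frequency (N(10, 0.8²) Hz, clipped to 8–12) with
hemisphere-specific gains g = √(1 ∓ LI_target(t)), so the expected
power-based LI equals the target. Gains are symmetric before cue onset.
Alpha phases are independent per channel — globally coherent alpha would
be removed by the common average reference, and posterior alpha is not
phase-locked across the scalp. The target LI is 0.12 in the alpha band
over the cue–target interval (0–2610 ms; the target appears 2610 ms after
cue onset: 50 ms cue + 2560 ms delay), modulated by piecewise gains over
the interval's thirds: (1, 0.25, 1) for control — the LI relaxes toward
zero mid-interval — and (1, 1, 1) for stress. These amplitudes are
calibration choices that make the headline contrast recoverable at desk
scale; they are not effect-size estimates. Cortisol: control sessions are
flat at 5 nmol/L; stress sessions rise from the 15-min sample to a peak of
baseline + δ at 20 min (δ ~ N(8, 4²) nmol/L, clipped ≥ 0) and decay
through 65 min, plus 0.5 nmol/L assay noise. The coupling ties the two
modalities: each subject's stress-condition LI boost inside 870–1535 ms
equals coupling_slope × ΔAUCi(true) + N(0, 0.05). Recordings use fixed
6.4 s trial slots (cue 1.8 s into the slot), so a default-size session is
about 31 minutes of signal; sessions should be streamed via
`iter_sessions` rather than held in memory. Everything is reproducible
byte-for-byte from (config, seed) via spawned seed sequences.

**Trial-power generator** (`synth.simulate_trial_power`). Repeated-study
calibration experiments (hundreds of studies) are infeasible through the
full 50-wavelet EEG path, so this generator draws studies directly at the
level the statistics consume: trial-wise contralateral/ipsilateral power,
pow = base · (1 ∓ L(f, t)) · exp(σ·z) with independent lognormal trial
noise per side (σ = 1.0), on a reduced 15 × 150 grid over 2–20 Hz ×
−500–3200 ms. The latent L carries the same structure as the full
generator (condition profiles, subject heterogeneity of SD 0.05, window
boost, ΔAUCi coupling with noise SD 0.08; ΔAUCi ~ N(260, 130²)
nmol/L·min, matching the noiseless AUCi of the cortisol profile at
δ = 8 ± 4). `coupling_slope_for_r` inverts the variance budget to the
slope that yields a requested latent ΔLI–ΔAUCi correlation (0.6 for the
recovery experiments). With all effect parameters zero, contra and ipsi
are exchangeable per trial, conditions are i.i.d. per subject, and ΔAUCi
is independent of ΔLI — so all three permutation nulls are exact by
construction and the measured rejection rates estimate the tests' true
type-I error.

**What the generators do not emulate** — and hence what passing tests do
*not* show about real data: volume conduction / head-model forward
projection; ocular and muscle artifacts (rejection stages are exercised
with constructed spikes only); temporal autocorrelation of trial-power
noise beyond what smoothing induces; non-Gaussian cortisol assay error;
behavioral responses. Calibration results transfer to real data only to
the extent that the exchangeability assumptions of each null hold there.

## Numerical choices

* Band-pass FIR: Hamming-window `firwin`, transition width = low_edge/2
  (0.5 Hz for the 1 Hz edge), giving ≥ 50 dB stopband one octave outside
  the band and < 1 dB passband ripple; applied as a single centered
  convolution of the symmetric kernel (exactly zero phase). Resampling via
  polyphase decimation (`resample_poly`).
* Robust z-scores for bad channels use median/MAD with the 1.4826
  consistency factor; a zero MAD (identical channels) flags nothing.
* Epoch time axes include both window endpoints; at 200 Hz the pruned
  −500…3200 ms axis has exactly 741 frames.
* The smoothing window (even length 50) covers [i−24, i+25]; edge windows
  shrink and renormalize, so constants are preserved exactly and convex
  bounds (LI ∈ [−1, 1]) are never violated.
* Zero-variance points in any statistic map are flagged NaN and treated as
  subthreshold; LI at zero total power is flagged missing and excluded
  from pair averages.
* Permutation engines accumulate per-subject contributions in float64;
  the cue engine's per-subject GEMM runs in float32 (the statistic is a
  t over subjects, far above single-precision noise).
* One master seed spawns independent per-stage streams (synthesis, each
  permutation test), so changing `n_perm` never changes the synthetic
  data; permutation p-values are deterministic given the seed.

## Problem sizes used by the shipped experiments

Calibration experiments run on the reduced grid with 12 subjects × 120
trials (type-I error, 200 studies), 20 subjects × 216 trials (condition
recovery, 50 studies) and 20 subjects × 108 trials × 3 pairs (coupling
recovery); the acceptance script uses the same designs at 100/25/25/100
repetitions plus one full-pipeline study of 6 subjects × 48 trials on a
12-channel montage. These sizes were chosen as the package's desk-scale
defaults; all are configurable.

## Known limitations

* The amplitude-only artifact criterion is a stand-in for the richer
  automatic criteria used in practice; its threshold (100 µV) is exposed
  as a parameter and should be tuned to the recording setup.
* The alpha band for bin tests and the Fisher-Z analysis (8–14 Hz) and
  the positive/negative-separate clustering convention are documented
  defaults, not identified quantities.
* The cue test's observed statistic contrasts the observed LI with one
  fixed surrogate draw per subject; a different surrogate draw changes the
  observed map slightly (the seed pins it). Averaging over many surrogates
  would reduce this Monte-Carlo component at proportional cost.
* The trial-power generator's lognormal noise is white across the grid;
  real time–frequency power is autocorrelated, which typically makes
  cluster tests *more* conservative at fixed pointwise threshold, so the
  measured type-I rates should be read as grid-specific calibration, not
  universal constants.
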