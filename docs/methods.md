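# Methods

`eegsurprise` implements a model-based analysis of expectation violation in
visual EEG. This note documents the models, the tunable parameters, the
synthetic-data generator, and the numerical choices, in enough detail to
judge what a passing test suite does — and does not — establish.

## Paradigm and design generation

Letter cues predict object images with 7:1 odds: per block, each of 8
cue–image pairs appears 7 times in its expected pairing and once with each of
the 7 other images, plus 16 vowel-cue no-go trials (128 trials/block; go
blocks use 7 expected repetitions, the behavioral learning variant uses 21,
i.e. 168 expected trials). Every image therefore serves equally often as
expected and as unexpected stimulus. Trial order is randomized under the
constraint that the same (cue, image) pair never repeats on consecutive
trials — including across no-go trials, a choice we make explicit because the
constraint's interaction with no-go trials is otherwise underdetermined.

Sequencing uses seeded shuffles with conflict-free swap repair of adjacent
duplicates, capped at 10,000 shuffles. Pure rejection sampling is adequate at
7 repetitions (~7% acceptance) but hopeless at 21 (~e^-14), hence the repair
step; the result still realizes the count matrix exactly and is deterministic
given the seed.

Stimulus-set selection maximizes J = z(var RDM_low) + z(var RDM_high) −
z(|corr(RDM_low, RDM_high)|), where variances are over off-diagonal RDM
entries, the correlation is over vectorized lower triangles, and z-scores are
taken across all evaluated subsets. Equal weighting of the correlation
penalty (after standardization) is our choice; the two variance terms are
weighted equally by construction. Exhaustive enumeration is used up to 10,000
admissible subsets, beyond that seeded random starts with single-item swap
hill climbing (standardization for the climb uses the initial random sample;
the final ranking re-standardizes over every subset visited).

## Feature models and surprise

All activation-based RDMs use Pearson correlation distance, d = 1 − r, with
an exactly zero diagonal; RDMs of multiple trained network instances may be
averaged element-wise. The semantic model embeds each category label in a
cluster of the label plus its 4 nearest words by cosine similarity (other
category labels excluded; optionally also their cluster members), and defines
between-category distance as the mean of 1 − cosine over all 25 cross-cluster
word pairs. The diagonal holds the mean over the 10 distinct within-cluster
pairs — a defined nonzero self-distance; no downstream consumer reads the
diagonal (RSA and surprise lookups use off-diagonal entries only), but it is
computed and stored. The task model is binary animacy (0 within category, 1
between). Cosine similarity of a zero vector is an error, not a default — a
silent convention would hide data bugs.

Trial-wise surprise under a model is the RDM entry between the cue-predicted
image and the image actually shown. The surprise design matrix holds one
5-vector (low-level, high-level, semantic, task, untrained control — fixed
order) per unexpected, correct, go trial; all other trials are excluded.

RDM vectorization everywhere is the lower triangle excluding the diagonal,
row-major.

## EEG preprocessing

Operations are deterministic epoch-level contracts: baseline correction
(default −0.7 to −0.5 s, the 200 ms before cue onset), zero-phase FIR
band-pass (default 1–60 Hz), z-score artifact rejection, average reference,
and ROI averaging over the 8 parieto-occipital electrodes (Oz, O1, O2, POz,
PO7, PO8, PO3, PO4).

The band-pass is a windowed-sinc (Hamming) kernel with transition width lo/2,
applied forward-backward. At 256 Hz and lo = 1 Hz the kernel (1691 taps)
is longer than a 1.8 s epoch, so the data are padded by one kernel length per
side with repeated odd reflection before filtering; this is the "with
padding" regime standard for epoched ERP filtering. Contract: passband
amplitude within 5%, ≥20 dB stopband attenuation on steady-state segments.

Artifact rejection z-scores two per-trial metrics across trials: peak-to-peak
amplitude on EOG channels (threshold z > 4) and the standard deviation of the
>30 Hz high-passed signal, maximum over scalp channels (threshold z > 8).
These are transparent stand-ins for toolbox-internal variance metrics and are
declared as such, not as replicas.

## Encoding (ERP scaling) analysis

Per participant and timepoint, single-trial ROI-averaged amplitude is
regressed (OLS with intercept) onto the five surprise regressors,
standardized to mean 0 / SD 1 across trials. Standardization makes betas
comparable across models on a shared axis; the scale factors are
recoverable from the design. Betas are smoothed with a Savitzky–Golay filter
(order 2, window 9 samples ≈ 35 ms at 256 Hz); edge samples use the
polynomial fit on the truncated terminal window (scipy `mode="interp"`), no
invented padding.

Group inference per model is a one-sample cluster-based permutation test:
samplewise t against zero, cluster-forming threshold at the two-tailed
p < .05 t quantile, cluster mass = summed t, and a null distribution of the
maximum |mass| over both signs (one family, matching two-tailed reporting)
from random per-participant sign flips. p_cluster = (1 + #{null ≥ observed})
/ (1 + n_perm); default n_perm = 100,000, with reduced counts in fast
profiles. Permutations are vectorized in chunks using the sign-flip identity
that squared data are flip-invariant, so only means need matrix products.
All-zero input yields an empty result (0/0 timepoints carry no evidence);
identical nonzero participants raise an error.

The Shapley R² decomposition attributes the regression's R² among correlated
regressors by exact enumeration over all 2^p subsets (p ≤ 12), satisfying
efficiency (attributions sum to the full-model R²), symmetry, and the dummy
axiom.

## RSA and onset latencies

Neural RDMs are computed per timepoint from stimulus patterns: go trials of
each stimulus are averaged within each recording block, the per-block channel
patterns are concatenated across blocks (e.g. 8 blocks × 64 channels = 512
dimensions), and entries are 1 − Pearson between stimulus vectors. A
per-block-RDM-then-average variant and a no-go-inclusion option exist behind
flags. Model comparison uses Kendall's tau-a (concordant − discordant over
n(n−1)/2); tau-b is available but unstable for the tied binary animacy model.
Tau timecourses are SG-smoothed and passed to the same cluster machinery.

Onset latency is the first crossing of 50% of the in-window maximum (window
0–200 ms), linearly interpolated between samples, measured on each
leave-one-out group average. Individual estimates are restored by
o_i = n·ō − (n−1)·O_(−i) with ō the mean of the leave-one-out scores, so the
restored estimates average exactly to ō and a paired t-test on them
reproduces the jackknife-corrected test. Curves that never cross the
criterion are flagged rather than silently dropped. The same machinery
applies to encoding-beta timecourses.

## ERP peak analysis and group statistics

Participant-specific peaks are the extrema of the ROI-averaged ERP in
canonical windows (P1 80–130, N1 130–190, P2 180–250, N2 200–300, P3 300–600
ms; positive for P components, negative for N), ties broken to the earliest
sample, windows clipped at epoch edges rather than erroring. Surprise betas
are averaged in ±10 ms around each participant's peak and tested against
zero: one-sample t, Cohen's d_z = mean/SD, Benjamini–Hochberg correction
across the full ERP × model family (paired contrasts correct within an ERP
across models), and a JZS Bayes factor with a Cauchy(0, 0.707) prior on the
standardized effect size. BF10 integrates the noncentral-t likelihood over
the prior by adaptive quadrature split at the likelihood peak (whose width
shrinks as 1/√n); an underflow band of scipy's `nct.pdf` far from the peak is
treated as zero. BF10 < 1/3 is read as evidence for the absence of an
effect.

Behavioral analyses: RTs (correct go trials within 100–1500 ms) and accuracy
per condition (expected / unexpected-same-response /
unexpected-different-response), one-way repeated-measures ANOVA with
Greenhouse–Geisser ε from the double-centered condition covariance (ε = 1
exactly at k = 2), Holm-corrected paired t-tests, and Morey-corrected
within-subject 95% CIs. A degenerate ANOVA (zero error variance, e.g.
ceiling accuracy everywhere) reports means with a null ANOVA rather than
failing the whole summary.

## Synthetic-data generator

The generator emulates the study conditions end to end. Defaults: 38
participants, 8 blocks × 128 trials, 64 channels at 256 Hz, epochs −0.8 to
1.0 s, a planted high-level-surprise amplitude modulation of 0.5 µV per SD of
surprise in 0.188–0.262 s, stimulus geometry following an equal-weight
low-level/high-level RDM mixture in 0.10–0.40 s at 3 µV pattern scale, AR(1)
noise (coefficient 0.3, stationary SD 5 µV), and behavioral targets of
511/516/526 ms and 96.4/96.1/95.1% per condition (lognormal RTs, Bernoulli
accuracy; RT SD 120 ms is our choice of a typical within-condition spread).

Each participant receives a *unique* stimulus set (feature banks, embeddings,
RDMs), as in the emulated design. This matters statistically: with only 28
lower-triangle entries per RDM, chance correlations between a "null" model
and the planted geometry are sizable, and if all participants shared one
stimulus set those chance correlations would be identical across the cohort,
biasing group-level RSA nulls. Unique sets turn them into zero-mean
participant-level noise.

Construction details:

* Cross-layer RDM control: the high-level RDM's lower triangle is an exact
  linear blend of the standardized low-level triangle and an orthogonalized
  random component (achieving the target correlation in-sample), mapped to
  distances 1 ± 0.3, and realized by features drawn via a Cholesky
  construction on the implied similarity matrix (nearest-PSD repair with
  re-checking when needed). Patterns produced this way are zero-mean and
  unit-norm rows, so sample Pearson correlations match the target exactly.
* Stimulus geometry uses the same exact-correlation construction over scalp
  channels with a raised-sine temporal envelope.
* Planted surprise increments ride on a zero-channel-mean topography (+1 on
  ROI electrodes, compensated elsewhere) and a 1–60 Hz band-limited boxcar
  profile. Both choices emulate physics — scalp potentials are reference-free
  and recorded EEG carries no sub-band energy — and make the planted effect
  invariant under average referencing and the pipeline's own band-pass. The
  band-limited profile has a shallow negative undershoot outside its window
  (as any band-passed unipolar deflection does); `effect_window_gain` reports
  the realized in-window mean of the profile (≈0.82 for the default window)
  for scale bookkeeping when comparing recovered betas to the planted
  coefficient.
* AR(1) noise is generated per trial/channel with innovation variance chosen
  for the target stationary SD. 1/f structure, channel covariance, eye blinks
  and drifts are *not* modeled: passing tests show the analysis recovers
  effects under temporally autocorrelated Gaussian noise, not under every
  artifact structure of real recordings.
* All randomness flows from one seed through named SeedSequence streams;
  identical specs give bit-identical outputs.

## Problem sizes

The full study scale (38 × 8 blocks × 64 channels × 1.8 s × 100,000
permutations) is the default of `GeneratorSpec`/`RunConfig`. The test suite
and the acceptance script exercise the pipeline at a reduced scale chosen to
keep the planted effect and its inference intact: typically 38 participants,
2 blocks, 16 channels, epochs −0.2 to 0.6 s (the planted 188–262 ms window
preserved), and 1,000–2,000 permutations; the cluster-test calibration uses
500 null cohorts of 38 × 60 timepoints. With 112 unexpected trials per
participant the planted 0.5 µV/SD effect has near-ceiling group-level power,
so detection rates estimate pipeline correctness, not marginal power.

## Known limitations

* The optimizer for stimulus selection is heuristic beyond 10,000 subsets; no
  optimality guarantee, only monotone improvement over the sampled pool.
* tau-a vs tau-b can differ slightly for tied model RDMs; tau-a is the
  default and recorded in provenance.
* The artifact-rejection metrics are declared substitutes for toolbox
  internals, not replicas; thresholds (4, 8) are kept.
* Real-data import (BrainVision/FIF) is a thin optional path through
  established readers; no continuous-data preprocessing (ICA, notch,
  interpolation) is reimplemented.
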