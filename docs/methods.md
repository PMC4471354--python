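# Methods

`attndecode` implements a complete single-trial pipeline for decoding
the direction (left vs. right) of covert visuospatial attention from
EEG alpha-band power, together with a synthetic session generator that
emulates a Posner-style cueing experiment with random-dot motion cues.
This note documents the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic tests do and do not
establish about real recordings.

## Experimental design emulated by the generator

A session comprises 8 blocks of 52 trials (416 total). Each trial shows
a central random-dot cue (400 dots, 250 ms), after which the subject
covertly shifts attention toward one of two lateral target locations;
the target appears 1.5–2.5 s after cue onset and the subject reports,
among other things, whether the target appeared at the location they
had attended. 75% of cues are *predictive* (coherent motion toward the
target side) and 25% are *ambiguous* (zero coherence); left/right
target sides and ±45° target orientations are balanced within each
condition by a largest-remainder allocation, ordered pseudo-randomly.

### Cue statistics

Dot directions are i.i.d. Von Mises with mean pointing at the target
side. We map "motion coherence" directly to the Von Mises concentration
κ: circular variance ≈ 1/κ for concentrated distributions, and κ = 0
gives the uniform distribution required for ambiguous cues. Ambiguous
cues are rejection-resampled (cap: 1,000 redraws) until the resultant
vector norm — the length of the mean unit vector of the dot directions
— falls below 0.05, so no usable direction information survives. The
default predictive concentration is κ = 1.29, the across-subject mean
coherence threshold reported for a 10% discrimination error rate.

### Behavior

The simulated subject attends the target side with probability
1 − spatial-error-rate for the cue's condition (defaults 10%
predictive, 50% ambiguous, so the overall unattended-target rate is
0.75·0.10 + 0.25·0.50 = 20%). Reports are truthful by default; a
`report_noise` flip probability probes label noise. Reaction times are
lognormal (median 0.75 s, shape 0.25), inflated multiplicatively by
1.35 when the target appears at the unattended location and by 1.30 on
ambiguous trials — positive, right-skewed, and simple to recover.
Target-identification errors are Bernoulli at 10% (attended) / 50%
(unattended). RTs are clipped at the 3 s response window.

### EEG forward model

The planted neural model has two alpha sources (8–14 Hz narrowband
Gaussian processes, source SD 20 μV) with fixed unit-norm topographies
peaking over left ({P7, P5, PO7, PO3, O1}) and right ({P8, P6, PO8,
PO4, O2}) posterior channels on a schematic 10-20 layout. The falloff
away from each group is Gaussian with scale 2.5 layout units, capped at
0.7 of the peak so the designated channels always carry the largest
coefficients. The wide falloff mimics volume-conduction smear and gives
the topography a strictly ordered gradient across all 64 channels;
a near-zero tail would make rank-correlation recovery of the planted
vector ill-posed, which is the statistic the package uses to compare
topographies.

Attention to one hemifield scales the ipsilateral source variance by
(1 + d) and the contralateral by 1/(1 + d) (default modulation depth
d = 1), so total power is class-balanced and only the lateralization
carries information. Source amplitudes carry lognormal per-trial jitter
(shape 0.2). Sensor noise is 1/f-shaped (flattened below 1 Hz),
spatially correlated with an exponential distance decay (scale 2 layout
units), per-channel SD 15 μV. Two bipolar EOG channels (hEOG, vEOG)
carry bounded sums of slow sinusoids (≤ 6 / ≤ 12 μV) plus 1 μV white
noise — by construction independent of the attended side, so EOG
features are an honest chance-level control. On a configurable fraction
of trials (default 1.5%, which reproduces the experiment's ~307.6/312
predictive and ~102.8/104 ambiguous post-rejection trial counts) a
half-cosine deflection (250 ms, 150 μV vertical or 60 μV horizontal)
is injected inside the pre-target epoch window; the bounded drift
guarantees that exactly the artifact trials cross the rejection
thresholds.

## Preprocessing

Common average reference over the 64 EEG channels (EOG untouched), then
a forward–backward Butterworth band-pass of order 4 at 8–14 Hz per
channel (zero phase; odd-reflection edge padding of 3× the filter
coefficient length, scipy's `filtfilt` default). Epochs cover the 1.5 s
before target onset — [onset − T, onset), half-open, 0-based, with
T = round(1.5 · sfreq) = 1536 samples at 1024 Hz. Epochs whose
mean-removed EOG reaches 100 μV (vertical) or 40 μV (horizontal) are
removed; "reaches" is inclusive (≥). Rejection uses the *broadband* EOG
within the epoch: the alpha filter would destroy the slow ocular
deflections the thresholds target. The alternative ordering (reject
before filter) is available behind a flag and selects the same epochs
under this convention. Labels are the attended side reconstructed from
the subjective report: the target side if the subject reported a match,
the opposite side otherwise.

## CSP with shrinkage covariances

Each epoch's covariance is estimated over time samples (per-channel
mean removed, divisor n) and shrunk toward the scaled identity
(tr(S)/N)·I with the closed-form oracle-approximating-shrinkage (OAS)
intensity, guaranteeing positive definiteness even for rank-deficient
epochs. Per-trial estimates are averaged per class without trace
normalization (a trace-normalized variant is out of scope; the
per-trial OAS intensities are recorded). The spatial filters solve
Σ_r W = λ Σ_l W via Cholesky whitening of Σ_l (`scipy.linalg.eigh`),
with eigenvalues sorted descending and filters normalized so
wᵀ Σ_l w = 1 — making λ_j exactly the right-class variance of filter j.
Patterns are A = (Wᵀ)⁻¹ = Σ_l W. Eigenvalue ties within 1e−10 are
ordered by the channel index of the largest pattern coefficient, a
deterministic tie-break. CSP-R1 is the pattern of the largest-λ filter,
CSP-L1 of the smallest; pattern signs are arbitrary, so topography
comparisons report a sign-aligned rank correlation alongside the raw
one. Features are log10 of the variance over time of each filtered
signal, computed for all N filters (selection is the decoder's job); a
zero-variance filtered signal yields −∞ and is flagged.

## Decoding

The classifier is an L2-regularized hinge-loss linear SVM (liblinear
dual). Feature-set size and the regularization parameter C are selected
jointly by recursive feature elimination inside stratified 10-fold
cross-validation: for each fold and each C, features are pruned by
squared-weight ranking while the *unregularized* mean hinge loss on the
held-out fold is recorded at every visited size; the (size, C) pair
minimizing the mean loss wins, ties resolved toward fewer features,
then smaller C. Final feature identities come from re-running the
elimination on all training trials at the chosen (size, C) — fold-wise
sets differ, so a consolidation rule is required. Features are always
centered and scaled with training-set statistics (CSP and EOG blocks
independently); zero-variance training features are dropped with a
warning.

Two evaluation protocols mirror the experiment:

- **Transfer**: CSP bank, selection, C, and scaling all derive from
  predictive trials only; the trained SVM decodes the ambiguous trials.
- **Within**: outer stratified 10-fold CV on predictive trials; the CSP
  bank is refitted and the inner RFE/CV selection re-run inside every
  outer training split, so no test statistic leaks upstream. The
  reported per-fold SD refers to the 10 outer folds. The consolidated
  `selected_features` is the union of fold-wise selections and
  `chosen_c` the modal fold choice (smallest on ties). A deliberately
  leaky path (bank fitted once on all trials) exists only as a
  diagnostic; tests demonstrate the inflation it produces on
  label-shuffled data.

Accuracy k/n is tested against the exact binomial upper tail
P(X ≥ k | n, 0.5), significant at p < 0.05. Per-feature class
differences use pooled-variance Student t-tests (right minus left;
Welch as an option). Pattern similarity uses Spearman correlation with
average ranks, two-tailed p via the t-approximation (adequate at
n = 64 channels); an exact permutation p is available for n ≤ 10.
Binary labels are encoded left = −1, right = +1 in all outputs.

## Numerical choices

- SVM solver: liblinear dual coordinate descent, `max_iter=300`,
  `tol=1e-3`, seeded. Fully converged fits at extreme C (the grid spans
  1e−5..1e5) cost up to two orders of magnitude more time inside the
  RFE × folds × C loop while changing the weight vector direction by
  < 0.2%; the capped setting is deterministic given the seed.
- The protocol's default decoding grid is 100 log-spaced C values with
  elimination step 1. Full-session analyses in the test suite and the
  examples use a reduced profile — 5 C values over 1e−2..1e2 with step 4
  (`DecodingConfig.fast()`), or 3 values with step 8 where noted — which
  selects from the same family of models at coarser resolution. Problem
  sizes used by the heavy checks: 10 default-geometry sessions (416
  trials, 64 channels, 1024 Hz) for parameter recovery; 160-trial
  sessions at 256 Hz for null calibration and monotonicity (3 seeds per
  modulation depth).
- Variances w'Sw are clamped at 0 before the log: they are mathematically
  nonnegative and tiny negatives are roundoff from rank-deficient
  epochs.
- The continuous signal is stored as float32 (a 416-trial session is
  ~300 MB); covariances and features are computed in float64.
- Degenerate inputs fail loudly: all-zero epochs, non-PD covariances
  (smallest eigenvalue reported), single-class label sets, constant
  vectors in rank correlation, out-of-range probabilities.

## What the synthetic tests show — and what they do not

Passing recovery tests show that the implementation correctly inverts
its own forward model: planted lateralized alpha sources are recovered
as discriminant-pattern topographies (|Spearman r| > 0.8), planted
behavioral rates are recovered within exact binomial intervals, and
null sessions (no modulation, shuffled labels, uninformative EOG)
decode at chance. The generator does not emulate non-stationary alpha
(drowsiness, blocks effects), non-alpha confounds (muscle, line noise),
volume-conducted source correlations, individual electrode geometry, or
genuinely eye-movement-contaminated neural activity; chance-level EOG
decoding here validates the control *analysis*, not the absence of
ocular confounds in any real recording. Real-data performance claims
require real data.

## Known limitations

- The within-condition protocol's RFE operates on features from a CSP
  bank fitted on the full training split, as in the original protocol;
  with very few trials and near-noiseless signals the inner selection
  can optimistically retain uninformative features (visible only far
  from realistic noise levels).
- The exact Spearman permutation p enumerates n! orderings and is
  limited to n ≤ 10.
- EDF/BDF ingest is a thin optional wrapper over `mne`; EDF export is
  not implemented.
- The coherence↔concentration convention is a documented package
  choice; published coherence values from other stimulus
  parameterizations may not map 1:1 onto κ.
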