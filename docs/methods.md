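# Methods

This note defines the quantities the `preictal` package computes, the
conventions and parameter defaults it uses, and what its synthetic
generator does and does not emulate. Nothing here makes empirical claims
beyond what the test suite and `scripts/acceptance.py` compute.

## 1. Preprocessing

Input is a multichannel scalp recording in microvolts. The standard chain
(`preictal.preprocess`):

1. **Montage** — select the 19 electrodes of the international 10–20
   system (Fp1…O2, with T3/T4/T5/T6 naming); electrode positions come from
   a template montage projected to the unit sphere.
2. **Resampling** to 250 Hz via polyphase filtering.
3. **Filtering** — zero-phase windowed-sinc FIR (Hamming), applied
   forward–backward: a 48–52 Hz band-stop for line noise, then a 1–40 Hz
   band-pass. Filter length ≈ 3.3·fs / transition-bandwidth taps (default
   transition 1 Hz), rounded up to odd.
4. **Artifact hook** — an optional user callback between filtering and
   referencing, the place to plug in ICA or regression-based artifact
   removal; the built-in path handles only gross channel failure.
5. **Average reference** — subtract the instantaneous channel mean.
6. **Bad channels** — a channel exceeding ±150 µV on more than 20 % of
   samples is replaced by spherical-spline interpolation (Perrin 1989,
   stiffness order 4, 20 Legendre terms, regularization 1e-5, zero-sum
   constraint), followed by re-referencing. If all channels are bad the
   recording is rejected.

Segmentation cuts non-overlapping epochs (default 3 s) inside annotated
state intervals; trailing partial epochs are discarded, gaps between
annotations contribute nothing.

## 2. Microstate analysis

**GFP.** For potentials V across n channels,
GFP = √(Σᵢ(Vᵢ − V̄)²/n) — the spatial standard deviation. Strict local
maxima of the GFP time course mark the high-SNR topographies used for
clustering.

**Similarity.** All map comparisons use the polarity-invariant absolute
spatial Pearson correlation |r| between average-referenced maps.

**T-AAHC.** Clustering starts from singleton clusters and repeatedly
*atomizes* the cluster contributing least global explained variance,
reassigning each freed map to the cluster whose centroid it correlates
with most strongly (|r|). Centroids are the dominant eigenvector of the
members' outer-product sum, which makes the procedure polarity-blind.
Cluster quality is measured by
GEV = Σₚ GFPₚ²·r²ₚ / Σₚ GFPₚ² over the clustered peak maps.

**Choice of k.** A meta-criterion runs the hierarchy once over an extended
range and ranks each k under three criteria: the marginal-GEV elbow, the
mean silhouette under the 1−|r| distance (on a subsample), and the
Krzanowski–Lai ratio with effective dimensionality n_channels − 1. The
selected k is the best median rank; ties resolve toward fewer maps.

**Backfitting.** Each sample of an epoch (normalized by the median GFP at
peaks) is labeled with the template of highest |r|; samples below the
minimum correlation 0.5 stay *unassigned* (label 0).

**Smoothing.** Runs shorter than 32 ms are split between their temporal
neighbors — the first ⌈len/2⌉ samples join the preceding run, the rest the
following; boundary runs are absorbed whole. Unassigned runs can donate
samples but never absorb them. The pass iterates to a fixed point.
Smoothing absorbs sub-threshold runs and therefore *inflates* mean
durations relative to the underlying dwell process; when an unbiased dwell
estimate matters (e.g. validating the generator), use the unsmoothed
sequence.

**Parameters.** Per class: mean duration (ms), coverage (fraction of
samples), occurrence (runs per second). Coverage sums to 1 over classes
plus the unassigned fraction; occurrence × duration ≈ coverage·1000 ms up
to boundary effects.

## 3. Complexity measures

**LZC.** The LZ76 exhaustive parsing counts the words in a left-to-right
factorization of the binarized signal (threshold at the mean, median or
mid-range; values ≥ threshold map to 1); a trailing incomplete word
counts. The count C_w is normalized to C_w/(N/log₂N), so finite random
sequences can slightly exceed 1.

**mLZC.** The same parser on the microstate label sequence, normalized by
default with the logarithm base equal to the alphabet size (4 classes →
log₄); base 2 is available behind a flag. Unassigned labels must be
removed first.

**PermEn.** Ordinal patterns of m consecutive samples (default m = 4,
delay τ = 1, stable argsort so ties break by position) give a pattern
distribution with Shannon entropy H; the reported value is H/ln(m!) ∈
[0, 1].

**mPermEn.** Microstate sequences repeat labels for tens of samples, so
adjacent duplicates are collapsed first; windows of m = k labels are then
indexed into the full mᵐ state-pattern space and the entropy is normalized
by ln(mᵐ) by default (the ln(m!) convention is available behind a flag).
A strictly alternating two-class sequence occupies exactly two patterns,
giving raw entropy ln 2.

## 4. Spectral features

Periodogram (boxcar window) power-spectral density times the bin width
gives bin powers whose sum equals the signal's mean square (Parseval).
Bands are half-open: δ [1,4), θ [4,8), α [8,12), β [12,30) Hz;
TBR = θ-power / β-power. Features are computed per channel and
channel-averaged; group tables stack condition × subject × band and
condition × subject × channel. Welch averaging is available behind a flag
for longer windows.

## 5. Prediction protocol

Per 3-s epoch, 23 named features: 12 microstate parameters (duration,
coverage, occurrence for classes A–D), 6 nonlinear (three LZC threshold
variants, mLZC, PermEn, mPermEn) and 5 spectral (four band powers + TBR).
Feature modes `fusion` / `microstate` / `nonlinear` / `spectrum` select
column families.

Evaluation: stratified 90/10 hold-out; on the training part, a pipeline of
standardization + RBF-SVM is tuned by 5-fold cross-validated grid search
(C ∈ 2⁻³…2⁷, γ ∈ 2⁻⁷…2³), refitted, and scored on the held-out split.
Standardization lives inside the pipeline, so its parameters are estimated
on training folds only — the held-out split never influences model
selection. The procedure repeats 10 times with split seeds
`protocol.seed + repetition`; reports give per-repetition metrics and
across-repetition mean ± sd for accuracy, sensitivity (preictal positive),
specificity, Cohen's kappa (all %), ROC AUC, and false alarms per
interictal hour (epoch-level counting; merging consecutive false positives
into single alarm events is available behind a flag).

## 6. Statistics

Paired comparisons first Shapiro–Wilk-test the differences (α = 0.05):
normal → paired t-test, otherwise Wilcoxon signed-rank (exact null
distribution for n ≤ 25 without zero differences, the standard
approximation otherwise). Effect size is paired Cohen's d =
mean(diff)/sd(diff, ddof 1). A feature is declared significant only when
p < α *and* |d| exceeds a threshold (default α = 0.0005, |d| > 0.3 for
feature tables). Kruskal–Wallis compares per-group map-count samples.

## 7. Synthetic generator

The generator plants exactly the structure the analysis assumes, so
recovery is a meaningful end-to-end test:

- **Label dynamics** — a semi-Markov chain over k classes: transitions
  from a stochastic matrix (default uniform off-diagonal), dwell times
  geometric (default, memoryless) or lognormal (σ = 0.5) with per-class
  mean 80 ms.
- **Topographies** — random low-order polynomials of the 3-D electrode
  coordinates, average-referenced and Gram-Schmidt-orthonormalized:
  smooth, zero-mean, pairwise spatial correlation exactly 0.
- **Envelope** — the active template is scaled by
  floor + (1−floor)·|sin(2πf t)| with f = 10 Hz and floor = 0.25, so the
  GFP oscillates and peaks (as real alpha-band EEG does) but the labeled
  topography never vanishes; a floor of 0 would erase label information
  twice per cycle and bias dwell estimates downward.
- **Background** — sinusoids at 2.5/6/10/20 Hz with random per-channel
  phase and gain, plus white noise scaled so the template-signal-to-noise
  ratio matches `snr_db` (default 20 dB).
- **Preictal effects** — per-class dwell multipliers (default 1.5, 1,
  1/1.5, 1), δ-amplitude ×0.7, θ-amplitude ×1.2, a 0.3 bias of the
  transition matrix toward a deterministic cycle (lowering label-sequence
  complexity), and optional epoch label noise. `strong_effects()` is a
  preset with deliberately large effects (2.0/1/0.5/1, δ×0.5, θ×1.6,
  bias 0.6) for separability demonstrations.

The generator emulates statistical structure, not biophysics: there is no
volume conduction model, no artifacts (eye blinks, muscle, electrode pops)
beyond stationary noise, no 1/f spectrum, and the preictal effects are
stylized, not fitted to patient data. Absolute classification numbers on
synthetic data therefore say nothing about clinical performance; they
verify the pipeline's mechanics and leak-freedom.

## 8. Numerical conventions and problem sizes

- All randomness flows through `numpy.random.default_rng` seeds carried in
  the spec/protocol dataclasses; identical seeds give byte-identical
  datasets and bitwise-reproducible reports.
- Binarization uses ≥ for the upper symbol; ordinal patterns break ties by
  position (stable sort).
- Typical validated problem sizes: 5-minute recordings (75 000 samples)
  for template recovery, 90-second recordings with ≤ 1200 subsampled GFP
  peak maps per run for k-selection, 60-epoch balanced datasets for the
  end-to-end protocol.

## 9. Limitations and open choices

- The placement and length of the preictal window relative to seizure
  onset is a study-design question the library does not answer; epochs
  inherit whatever state annotations the recording carries.
- T-AAHC is deterministic given the map sample, but the GFP-peak
  subsample is random; template polarity and class order are arbitrary
  (classes are matched to references by |r| when needed).
- The exact Wilcoxon path requires untied, nonzero differences; ties fall
  back to the approximate method.
- mLZC/mPermEn normalization conventions differ across the literature;
  both common choices are implemented, with the defaults stated above.
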