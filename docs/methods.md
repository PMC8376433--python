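# Methods

This note documents the models, discretizations and design choices behind
`doaeeg`, in the spirit of a methods appendix: what each stage assumes, which
parameters matter, and what the synthetic experiments do and do not show.

## Preprocessing

Raw recordings are multichannel scalp EEG (nominally 1000 Hz, microvolts)
with a parallel BIS trace on the monitor's own clock. Per channel the
cleaning chain applies:

1. a zero-phase 4th-order Butterworth band-pass, 0.5–70 Hz (the high-pass
   removes drift, the low-pass high-frequency noise). Zero-phase filtering
   (`sosfiltfilt`) is used so that no group delay shifts epoch boundaries;
   its cost is that the effective magnitude response is squared.
2. a zero-phase IIR notch at 50 Hz, quality factor 30, for mains
   interference.
3. decimation to 100 Hz. The decimator applies its own anti-aliasing
   low-pass below the new 50 Hz Nyquist regardless of the earlier 70 Hz
   low-pass; without it, content between 50 and 70 Hz would fold into the
   band of interest.

Epochs are 30 s with 50 % overlap; a trailing window that would overrun the
recording is dropped. Each epoch's label comes from the mean BIS over its
span, with the BIS trace linearly interpolated onto the epoch's time axis
because the two clocks are not synchronized. Boundary convention: BIS 40 and
60 both map to A, since D is defined by "below 40" and S by "above 60".
Manual artifact screening is replaced by a reproducible amplitude-threshold
rejecter (default ±150 µV, configurable, can be disabled): any epoch whose
peak absolute value exceeds the bound on any channel is discarded.

## Time-frequency maps

The Wigner–Ville distribution (WVD) of the analytic signal is discretized
with the half-lag trick: K[n, m] = y[n+m]·y*[n−m] corresponds to lag
τ = 2m/fs, and an `n_freqs`-point DFT over m yields frequencies
k·fs/(2·n_freqs) on [0, fs/2). Design details:

- **Lag truncation.** Lag products are truncated at epoch boundaries (no
  reflection); edge bins are excluded from property tests. The usable
  half-lag extent is additionally capped at `n_freqs/2 − 1` so positive and
  negative lags cannot collide in the DFT buffer — a frequency grid of 256
  points therefore implies at most 127 half-lags even if the configured
  `h_len` (default ≈ N/4, odd) is longer.
- **Windows.** h (lag window, frequency smoothing) and g (time window) are
  rectangular; g is normalized to unit sum and applied as a centered moving
  average (cumulative-sum implementation, zero-padded at the edges).
  Defaults for a 3000-sample epoch: h_len = 751, g_len = 187. With
  g_len = 1 the SPWVD reduces exactly to the PWVD, and with full lag support
  the PWVD reduces exactly to the WVD; both identities are tested to 1e-9.
- **Scaling.** Values carry a 2/fs factor so the frequency marginal of a
  column returns instantaneous power and total map energy equals signal
  energy (tested to 5 %).
- **Time subsampling.** Maps are evaluated every `time_step` samples
  (default 25, i.e. 0.25 s per pixel at 100 Hz). The time-smoothing window
  spans ≈ 1.9 s, so finer sampling yields near-duplicate neighboring
  columns; for texture analysis that would make distance-1 co-occurrence
  pairs nearly degenerate and wash out class differences. 0.25 s per pixel
  keeps adjacent pixels informative while bounding cost.
- **Band crop.** The pipeline crops maps to [0, 8] Hz before texture
  extraction (anesthetic EEG has negligible energy above 8 Hz); a flag
  disables cropping. An STFT spectrogram is available as a cheap comparator
  map on the same axes convention.

## Texture features

Each (cropped) map is treated as an image with rows = frequency and
columns = time, min–max quantized into L = 16 equal-width gray levels
(per-map, so features are invariant to any positive rescaling of the map; a
constant map quantizes to level 1). The GLCM accumulates co-occurrence
counts at distance 1 over four orientations (0°, 45°, 90°, 135°),
symmetrically, pooled before normalization — an orientation-robust common
default; with it, the four features are insensitive to transposing the
image. Contrast, correlation, energy and homogeneity use the standard
Haralick definitions; correlation returns 0 for the degenerate single-level
image. 16 gray levels is the default because coarser quantization merges
distinct activity levels while much finer quantization dilutes the
co-occurrence mass.

The per-channel 4-vectors are concatenated in montage order
(Fp1 … P4) into the 60-dimensional epoch feature vector.

## MRMR feature ranking (MIQ)

Features are discretized per column into 10 equal-width bins (top edge
closed; equal-frequency binning available, under which mutual information is
invariant to monotone feature transforms). Mutual information is the plug-in
estimate on the empirical contingency table, in bits by default. The forward
selection: seed with the most relevant feature; while any unselected feature
has nonzero relevance and zero redundancy with the selected set, add the
most relevant such feature; then repeatedly add the feature with the largest
relevance/redundancy quotient among those with nonzero relevance; finally
append zero-relevance features in seeded-random order. "Zero" means below
ε = 1e-12: a plug-in estimate of an independent pair is positive almost
surely, so a literal zero would leave the zero-redundancy and zero-relevance
phases dead on real data (a permutation-null option exists for relevance
screening). Argmax ties break toward the lower feature index. The number of
retained features defaults to 30 (half of 60) and is configurable.

## KNN classification

Eight distance metrics: Euclidean, standardized Euclidean (per-dimension
scaling by training standard deviations, floored at 1e-8 for constant
features), Minkowski (p ≥ 1), Chebyshev, city block, cosine, correlation and
Mahalanobis. The Mahalanobis covariance is estimated from the training fold
only and ridge-regularized (λ = 1e-6 · trace/dim) when its condition number
exceeds 1e10, which matters when tens of correlated features meet few
hundred samples. K defaults to 5 (the operating point's neighbor count is
not uniquely dictated by theory; it is exposed and sweepable). Vote ties
break toward the class with the smaller summed neighbor distance, then
toward the earlier class in D < A < S order.

## Augmentation and evaluation

Within each training fold, features are z-scored on training statistics and
each training row receives m = 35 Gaussian-noise copies with variance 0.1
per coordinate. Standardizing first is what makes a single absolute variance
meaningful across features whose raw scales differ by orders of magnitude.
Test rows are never augmented — a provenance flag travels with every row and
the cross-validation driver asserts that augmented rows stay inside the
training model. MRMR and the scaler are re-fit inside each fold to avoid
leakage of test statistics (possibly stricter than older practice, but the
defensible default). Folds are a seeded random partition into 10 near-equal
parts; if a training fold happens to miss a class the driver warns and
refits with stratified folds. Reports carry the pooled 3×3 confusion matrix
(rows = actual D, A, S), accuracy = 100·trace/total, and per-class
sensitivity = 100·diagonal/row-sum. A sweep helper runs cartesian parameter
grids with shared fold seeds, and a per-subject driver evaluates each
subject independently (the natural grouping for clinical recordings).

## Synthetic data: what it emulates, and what it does not

Each recording is built per channel as pink (1/f-amplitude) background
noise plus band-limited Gaussian oscillators, scaled so the 99th percentile
of |signal| is ≈ 85 µV, with an optional 50 Hz mains component and a BIS
trace drawn inside the class's own bracket (so BIS-derived labels are
consistent by construction). Half of each oscillator's variance comes from
sources shared across channels and half is channel-private, giving realistic
but imperfect inter-channel correlation; per-channel gains jitter by ±20 %
per recording. Default class recipes:

- **D**: 0.5–2 Hz oscillator, gain 3.0 — dominant slow rhythms.
- **A**: 0.5–4 Hz gain 1.8 plus 4–8 Hz gain 1.2 — the strongest, broadest
  0–8 Hz activity. Two band sources are used rather than one wide band so
  the whole range is genuinely occupied.
- **S**: 2–8 Hz gain 1.0 plus weak 8–20 Hz (gain 0.5, mostly removed by the
  8 Hz crop), with the pink background halved — lighter anesthesia carries
  less slow-wave drift, and this is also what makes S texturally
  distinguishable from D: co-occurrence statistics are position-agnostic, so
  classes must differ in map occupancy and granularity, not merely in which
  band is active.

These defaults were calibrated once so that the three classes are separable
by the pipeline at its operating point while identical profiles collapse to
chance; they are configuration, not fitted parameters.

Not emulated: drug kinetics, state transitions within a recording,
eye-blink/EMG artifacts, electrode drift, volume conduction. Passing the
end-to-end test therefore demonstrates pipeline correctness and
class-recovery capacity under the stated spectral model — not clinical
performance on operating-room data.

**Recording-identity leakage.** Epochs cut from one recording share that
recording's gain draws and, with 50 % overlap, half their samples. Under
random (non-grouped) cross-validation a KNN can therefore match a test epoch
to same-recording neighbors. On the default dataset this inflates accuracy
only mildly (leave-recording-out evaluation stays within a few points of
random folds, so the recovered signal is genuinely spectral), but a chance
baseline must not contain it: the identical-profile baseline therefore uses
30 s recordings contributing one epoch each, removing any recording-level
fingerprint. Grouped folds are available via the per-subject driver for
users who want leakage-free estimates on real data. Note that the baseline
can sit a few points *below* 1/3: under cross-validation at chance, the
held-out sample's own class is always slightly underrepresented in the
training fold, and nearest-neighbor voting amplifies that pessimistic bias
at small sample sizes.

## Problem sizes and reported quantities

The default synthetic experiment uses 60 epochs per class (recordings of
120 s at 1000 Hz, seven epochs each), 10-fold CV at the operating point
(SPWVD, L = 16, MRMR top-30, K = 5 Mahalanobis, m = 35, variance 0.1). The
acceptance script additionally recomputes, from the stored six-subject
confusion counts of the original clinical study, every derivable printed
number (per-subject accuracy, per-class sensitivity, average and minimum
accuracy, epoch totals) using the same report-arithmetic functions the
evaluator uses. Two published sensitivities (subject 6) are printed
truncated rather than rounded; the regression test's tolerance (0.015)
accounts for that.
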