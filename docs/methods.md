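# Methods

This note records the signal-processing and statistical conventions the
package commits to, the places where a definition was genuinely open and
a choice had to be made, and what the synthetic-data experiments do and
do not demonstrate.

## Pre-processing

Channels are filtered with a Butterworth band-pass (10–500 Hz) followed
by a second-order IIR notch at 50 Hz (Q = 30).  The band-pass order
defaults to 4 and both filters are applied forward-backward, so the
effective magnitude response has order 8 and zero phase — phase
distortion would bias shape-sensitive features (slope sign changes,
Hjorth parameters, waveform length).  Single-pass filtering is available
via `FilterConfig(zero_phase=False)` for causal/online emulation.

Contraction trimming removes `round(L * fraction / 2)` samples from each
end of every schedule entry (default fraction 0.30, i.e. 15% per end),
discarding the transition periods around contraction onset/offset.
Trimming applies to rest entries too: rest is a first-class movement
class and receives symmetric treatment.

Windowing is per schedule entry: offsets 0, step, 2·step, … while the
window fits inside the entry, so windows never straddle a class
boundary and label purity is guaranteed.  The per-entry window count is
`floor((L - N)/step) + 1`.  At 2000 Hz with 200 ms / 100 ms settings,
N = 400 and step = 200 samples.  Sample indices are 0-based and
intervals half-open throughout.

## Time-domain features

The 25 TD features follow the conventional definitions, with these
commitments where definitions vary in the literature:

* **Signal power (`VAR`)** is `sum(x^2)/(N-1)` *without* mean
  subtraction.  Band-passed EMG is essentially zero-mean, and this form
  doubles as the Hjorth activity parameter.  The Hjorth mobility and
  complexity parameters, by contrast, use the conventional
  mean-subtracted sample variance internally — a deliberate divergence,
  since the mobility of a non-centred signal is not the spectral-spread
  proxy Hjorth defined.
* **Zero crossings** count adjacent pairs with strictly negative
  product; exact zeros never count (`sgn(0) = 0`).
* **Peak statistics (`NP`, `MPV`, `MFV`)**: peaks are raw samples
  strictly greater than the window RMS (a threshold-exceedance reading,
  not local maxima).  `MFV` is the mean of successive peak differences;
  fewer than two peaks give 0.
* **Slope sign changes** and **Willison amplitude** use configurable
  thresholds, both defaulting to 0 (`ThresholdConfig`).
* **Curve-length fractal measure (`FDIM`)** uses 0-based indexing with a
  single offset (no offset averaging): stride-k curve length scaled by
  `(N-1)/(N k)`.  The stride for the standalone `FDIM` feature column
  defaults to k = 1 (the finest scale, and the anchor the Higuchi
  dimension uses); it is configurable.  The Higuchi fractal dimension is
  the log-log slope between strides 1 and `kmax` (default 10).  On a
  400-sample linear ramp this yields 1.0099, the expected dimension of a
  line up to the floor-induced bias at stride 10.
* **75th percentile** is nearest-rank on the raw (signed) sample values:
  the sorted sample at index `floor(0.75 N)`.
* **Amplitude histogram** uses 9 equal-width bins spanning the
  per-window `[min, max]` range (the last bin right-closed).  Nine bins
  make the full TD block exactly 133 columns on 4 channels
  (22 scalars x 4 + 6 channel-pair correlations + 3 energy ratios +
  9 bins x 4).
* **Channel-pair correlation** is the absolute Pearson correlation
  (result in [0, 1]); constant channels return 0 with a warning.
* **Energy ratios** with 1-based channel numbering are
  `ER_jk = E_j E_1 / E_k^2` for j = 2..M-1, k = j+1..M — 3 values for
  4 channels.
* **MAV slope** assigns the forward difference `MAV_{i+1} - MAV_i` to
  window i within each contraction, with 0 for the final window, keeping
  the per-window arity at 1.

Degenerate windows (constant samples) yield NaN with a logged warning
for variance-normalised features; features whose true limit is zero
(WL, DAMV, DASDV) return 0.

## Frequency-domain features

All FD features are computed on the unpadded FFT of the window
(Δf = fs/N = 5 Hz at the defaults).  Statistics with a physical
frequency axis — mean frequency, median frequency, spectral peak
mean/STD, frequency ratio, peak frequency — use the one-sided spectrum;
the spectral waveform length and the frequency-energy vector use the
full two-sided array.

* **Median frequency** is the smallest bin at which cumulative power
  reaches half the total (with a 1e-12 relative slack so a bin holding
  exactly half wins the tie).
* **Peak frequency** is the argmax of power; near-ties within 1e-9
  relative resolve to the lowest frequency, making equal-amplitude tones
  deterministic under FFT round-off.
* **Frequency ratio** uses low band [10, 250) Hz and high band
  [250, 500] Hz by default (matching the pre-filter passband split); a
  high band holding only round-off power (≤ 1e-12 of the total) is
  treated as empty and yields the error sentinel.
* **Frequency energy (`FE`)** sums squared two-sided FFT amplitudes into
  contiguous 10 Hz bins over the full 0–fs axis: 200 bins per channel
  for 400-sample windows at 2000 Hz, which is what makes the full FD
  block 828 columns (7 scalars x 4 channels + 200 bins x 4).  The DC bin
  is included; bin sums conserve total spectral energy exactly.

## Time-frequency features

Level-4 decompositions with periodization boundary handling: a DWT with
the 4th-order Coiflet (`coif4`) and a full wavelet-packet tree with the
5th-order Symmlet (`sym5`).  Periodization keeps exactly `N/2^4 = 25`
coefficients per band, making the Parseval identities exact to float
tolerance and the normalised-log-energy denominator exact.  (The MATLAB
boundary convention used in older toolboxes is not recoverable from
published descriptions; periodization is the choice that preserves the
counts and energies.)

The eight DWT statistics (STD, power, waveform length, energy, max
absolute value, zero crossings, mean, MAV) are applied to the
concatenated `[A4, D4]` last-level coefficient vector — the feature
values are scalars, so this convention does not affect the block width.
The three packet features (log RMS, relative energy, normalised log
energy) are computed for each of the 16 level-4 subspaces, in frequency
order, with natural logarithms.  Identity `NLE = 2 * LogRMS` holds
exactly and is regression-tested.  Total: 8 x 4 + 3 x 16 x 4 = 224
columns.

## Dimensionality reduction

Sequential selection is the literal two-pass scheme: pass 1 walks the
candidate blocks in their canonical order and keeps a block iff the
cross-validated accuracy *strictly* increases; pass 2 walks the kept
blocks in inverted order and removes a block iff accuracy does not
decrease.  The empty-set baseline is chance (1/n_classes), so the first
informative block always enters.  The evaluator is injected, so
selection can be driven by any classifier and either accuracy statistic.

PCA (default 20 components) standardises each column to zero mean / unit
variance before projection — TD blocks span wildly different scales
(counts, millivolts, logarithms), and unstandardised PCA would be
dominated by the histogram counts.  Zero-variance columns get scale 1
with a warning.  The projection is always fitted on training rows only.

## Classifiers

* **LDA**: shared-covariance Gaussian discriminant (scikit-learn SVD
  solver).
* **KNN**: k = 2, Euclidean, distance-weighted votes.  With k = 2,
  distance weighting acts only when the two neighbours disagree, which
  implements "ties broken by the nearer neighbour" exactly and makes
  k = 2 well defined.
* **DT**: binary CART with Gini impurity, unlimited depth, minimum leaf
  size 1.
* **MLE**: implemented in-package — per-class mean and full ML
  covariance, equal priors, argmax log-density via Cholesky solves.
  Singular covariances receive an isotropic ridge `1e-6 * trace/d`.
  Predictions are cross-checked in the test suite against direct
  `scipy.stats.multivariate_normal` density evaluation.
* **SVM**: RBF C-SVC; C and gamma chosen by an inner 3-fold grid search
  over C ∈ 2^{-5..15}, γ ∈ 2^{-15..3} (step 2²).  The grid is
  conventional and config-exposed; tests use a reduced grid to keep
  runtimes sensible.
* **MLP**: two tanh hidden layers of 16 units.  Bayesian-regularised
  training (a MATLAB-specific scheme) is replaced by L2 weight decay
  (α = 1e-3) with early stopping; the optional `sgd` solver retains
  learning rate 0.1 and momentum 0.1.

KNN, SVM and MLP inputs are z-scored with training-split statistics
(config-toggleable); LDA, DT and MLE operate on raw features.

## Evaluation protocol

Stratified 10-fold cross-validation within each subject (shuffled with
the run seed); fold accuracies are averaged per subject, then across
subjects; confusion counts are pooled.  Folds are random over windows —
faithful to the standard offline protocol even though 50%-overlapping
windows make neighbouring windows near-duplicates, which inflates
absolute accuracies (see limitations).

Two statistics are reported side by side because they measure different
things.  The TN-inclusive class-wise accuracy `(TP+TN)/(TP+TN+FP+FN)`
averaged over classes is dominated by true negatives when there are many
classes (its chance level for 11 balanced classes is ≈ 85%).  The mean
per-class recall — the diagonal average of the row-normalised
performance matrix — is the statistic printed under published
performance matrices (the three reference tables shipped in
`emgpr.benchmarks` reproduce 97.43%, 90.0% and 95.47% as their diagonal
means) and has chance level 100/11 ≈ 9.09%, which is why the
label-shuffling null checks use it.

Wall-clock train/test times are accumulated per fold with
`time.perf_counter`.  Times are hardware-dependent and excluded from any
determinism comparison; all statistical content (accuracies, confusion
counts) is byte-reproducible given the seed.

## Synthetic sessions

The generator models each contraction as band-pass-filtered white
Gaussian noise (order-8 Butterworth shaping, ≥ 90% of power in the
configured band), scaled per channel by a class-specific gain pattern, a
per-contraction amplitude jitter, and a slow (~1 Hz) within-contraction
amplitude wobble, on top of a white noise floor.  Contractions are laid
out in repeated class cycles with unlabelled gaps; rest is an explicit
low-amplitude class, so all 11 classes are balanced.  This
colored-noise-times-envelope model reproduces exactly the statistical
structure the features measure — amplitude distribution, spectral
content, waveform complexity — at trivial cost, in place of a
physiological motor-unit simulation.

The *easy* preset (default 3 repetitions of 3 s contractions; 60 windows
per class after trimming) gives every class a distinct gain pattern and
band with 5% jitter: classes are separable by construction and the
`FS`/MLE combination reaches ≥ 90% (in practice ~100%) mean recall.  The
*hard* preset compresses the gain and band differences to 20% of the
easy spread, widens the jitter to 45% and the amplitude wobble to 60%,
and raises the noise floor — calibrated so cross-validated accuracies
land mid-range (roughly 55–70%) for contrastive tests.

What passing these tests shows: the pipeline preserves and exploits
class information carried by amplitude and spectral shape, and collapses
to chance when labels carry no information.  What it does not show:
performance on real EMG, which additionally exhibits motor-unit
structure, nonstationarity within contractions, electrode shift,
crosstalk and fatigue — none of which the generator emulates.  Absolute
accuracies on the easy preset are therefore not comparable to accuracies
on clinical recordings.

## Problem sizes

The default test and acceptance runs use one synthetic subject per
session: 11 classes x 3 repetitions x 3 s contractions at 2000 Hz
(660 windows), the 22-column `FS` set for pipeline-level checks, and
2-window assemblies for the full 133/828/224-column dimension checks.
These sizes were chosen so the whole suite exercises every stage in
seconds while keeping ≥ 50 training windows per class per fold.

## Known limitations

* Native session formats of public EMG databases (e.g. MATLAB `.mat`
  containers) are not parsed; CSV and multi-channel WAV are the
  interchange formats.  WAV round-trips at float32 precision.
* Random fold assignment over overlapping windows leaks near-duplicate
  windows between train and test; a contiguous-block fold option would
  reduce this but is deliberately not the default, to match the
  standard offline protocol this package mirrors.
* The frequency-energy block width depends on fs and N (200 bins per
  channel only at 2000 Hz / 400 samples); feature matrices from
  different window configurations are not column-compatible.
* Error sentinels are NaN; downstream classifiers do not impute, so
  degenerate windows (flat lines) must be filtered out by the caller.
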