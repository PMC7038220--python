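# Methods

## Problem and pipeline

`bispeeg` implements a two-class EEG screening pipeline whose discriminative
signal is *quadratic phase coupling* (QPC): three oscillations at f1, f2 and
f1+f2 whose phases satisfy phi3 = phi1 + phi2. Phase relations are invisible
to second-order statistics (the power spectrum discards phase), but they
produce a peak of the third-order spectrum, the bispectrum

    B(f1, f2) = E[ X(f1) X(f2) X*(f1 + f2) ],

at the bifrequency (f1, f2). The pipeline renders each EEG segment's
bispectrum magnitude as a gray-level image, summarises that image with
texture and entropy statistics, reduces the per-subject feature vectors with
locality sensitive discriminant analysis (LSDA), keeps the components that
pass a two-sample Welch t-test at p < 0.05, and classifies subjects with a
probabilistic neural network (PNN) or one of the delegated baselines (LDA,
QDA, KNN, SVM with RBF or polynomial kernels), evaluated by stratified
10-fold cross-validation with confusion counts pooled over held-out folds.

## Preprocessing

Recordings (channels x samples, microvolts, 500 Hz by default) are band-pass
filtered to 0.3–40 Hz with a zero-phase order-4 Butterworth filter
(`sosfiltfilt`, forward–backward). Zero-phase filtering matters here: the
downstream statistic is phase-sensitive, and a causal filter's
frequency-dependent phase lag would distort the very phase relations the
bispectrum measures. The forward–backward padding is extended to about three
periods of the low cutoff (min(n-1, 3·fs/lo) samples) because the default
`sosfiltfilt` padding is far too short for a 0.3 Hz edge and leaves large
start-up transients. Each channel is then cut into non-overlapping
5519-sample segments (~11 s at 500 Hz); the trailing remainder is discarded.
Segment offsets are 0-based half-open windows; channels are processed
independently with no re-referencing or artifact handling.

## Bispectrum estimation

The direct (FFT) estimator: each segment is cut into `block_len = 512`
sample blocks with 50% overlap, each block is mean-removed and Hann-tapered,
and the triple products X_k(f1) X_k(f2) X_k*(f1+f2) are averaged over the K
blocks on the square bifrequency grid f1, f2 in [0, fs/2] (nfft = 512, about
1 Hz per bin at 500 Hz; a 5519-sample segment yields K = 20 blocks). Bins
with f1 + f2 > fs/2 are outside the estimable region and set to zero; the
non-redundant principal triangle (0 <= f2 <= f1, f1 + f2 <= fs/2, boundary
included) is available as a mask and config option, but features default to
the full symmetric half-grid so the image retains the estimator's symmetry
B(f1,f2) = B(f2,f1). Block averaging is what separates genuine coupling from
chance alignment: for an uncoupled triplet the triple product has random
phase per block and cancels, while a coupled triplet adds coherently.
Rao–Gabr smoothing is available but off by default. Scaling the input by a
scales |B| by a^3 exactly.

## Gray-level imaging

The magnitude is compressed and quantized to `G = 64` gray levels by
min–max scaling of log10(|B| / max|B| + 1e-6), floor-quantized with the top
value clamped to G-1; a constant magnitude maps to level 0. The *relative*
log was chosen over log1p(|B|) deliberately: |B| scales with the cube of the
signal amplitude, and dividing by the peak before the log makes the
quantized image exactly invariant to per-subject amplitude differences
(gain, electrode impedance), which log1p of absolute values is not. The
1e-6 floor bounds the displayed dynamic range at six decades, a typical
bispectrum display range. G = 64 balances run-length statistics against
sparsity of the histogram.

## Texture and entropy features (18 per image)

Eleven gray-level run-length matrix (GLRLM) statistics with the standard
Galloway/Chu/Dasarathy–Holder definitions — SRE, LRE, GLN, RLN, RP, LGRE,
HGRE, SRLGE, SRHGE, LRLGE, LRHGE — computed per direction (0, 45, 90,
135 degrees) and averaged over the four directions (the usual radiomics
convention; the direction set is transpose-closed, so features are invariant
to image transposition). Inside the formulas the gray index i and run-length
index j are 1-based (levels 0..G-1 shift to 1..G). Runs are maximal
collinear constant-level pixel sequences; every pixel belongs to exactly one
run per direction, giving the conservation law sum_ij j·P(i,j) = n_pixels
that the property tests enforce.

Seven histogram measures on the normalised G-bin gray-level histogram p:
log energy sum log2(p^2 + 1e-12), Shannon entropy, Renyi entropy of order
alpha = 2, Kapur's two-parameter entropy (alpha = 0.5, beta = 0.7),
min-entropy -log2 max p ("max entropy"), quadratic/Gini entropy
sum p(1-p) ("Vajda"), and Yager's fuzziness complement 1 - sum|2p-1| / G.
Zero-probability bins are skipped in logarithmic sums. The literature does
not pin unique definitions for several of these names; the choices above are
declared defaults and every definition can be swapped via
`EntropyConfig.overrides` without touching callers. Entropies are computed
on the quantized image's histogram (not on raw |B|) so both feature families
see the identical input.

## Reduction and selection

Per-subject vectors (mean of the 18 features over all channels and segments
of a subject) enter LSDA. Features are z-scored with training statistics
first: run-length emphases span several orders of magnitude, and the
Euclidean kNN graph underlying LSDA would otherwise be dominated by the
largest-scale feature. LSDA builds a k = 5 nearest-neighbour graph, splits
each neighbourhood into same-label (Ww) and different-label (Wb) edges, and
solves the generalized eigenproblem

    X (alpha·Lb + (1-alpha)·Ww) X^T a = lambda · X Dw X^T a,

Lb = Db - Wb, alpha = 0.5, keeping the top-d eigenvectors (d defaults to 30
and is clamped to min(n_features, n_samples - 1); with 18 input features the
default pipeline yields 18 components). Numerical choices: the constraint
matrix gets an automatic trace-scaled ridge (1e-8, escalated and logged if
the generalized solver still fails); eigenvectors get a deterministic sign
(largest-magnitude coefficient positive); ties in eigenvalue sorting are
broken stably.

Selection is a per-component two-sample Welch t-test — unequal variances,
t = |m2 - m1| / sqrt(s1^2/n1 + s2^2/n2) with Welch–Satterthwaite degrees of
freedom — keeping components with p < 0.05 ordered by ascending p. Welch
rather than the pooled-variance test is the default because recomputing the
reference table's t values from its printed group summaries with n = (37, 40)
matches the printed values only under Welch; the pooled variant is available
by config. The un-equal-variance choice matters for nothing downstream
except the exact t values. No multiple-testing correction is applied (the
modelled procedure uses raw p < 0.05); this is a known statistical caveat.
By default the whole supervised reduction (z-scoring, LSDA fit, t-test,
selection) is refitted inside every training fold of the cross-validation
— the leakage-free mode — with a `global` single-fit mode available for
table-style reporting. Under a zero-contrast null the selection stage
retains ~5% of components (the supervised-but-local LSDA fit barely inflates
the t statistics; verified by a calibration test over 50 null cohorts). If
no component passes the threshold the single best-ranked component is kept
(logged) so the classifier always has an input.

## Classification

The PNN is a Parzen-window kernel density classifier: class score
g_c(x) = (1/N) sum_{i in c} exp(-||x - x_i||^2 / (2 sigma^2)), i.e. the
class-conditional density times the empirical class prior, predicting the
argmax with ties to the first-seen class. The prior factor gives the two
correct limits — 1-nearest-neighbour as sigma -> 0 and training-majority
vote as sigma -> infinity — that a bare class-mean score does not. Scores
are rescaled per test point by the nearest-training-point kernel so tiny
sigmas cannot underflow (argmax, ratios and normalised probabilities are
unchanged). Sigma defaults to a deterministic inner 3-fold grid search over
16 log-spaced values in [0.01, 10]; that range refers to standardized
features, so PNN (like KNN and the SVMs) is wrapped with a per-training-fold
standard scaler. SVM defaults: C = 1; polynomial kernels (degree 1-3) use
gamma = 1/n_features and coef0 = 1; RBF uses scikit-learn's `scale` gamma.
LDA/QDA are scale-equivariant and used unwrapped.

Evaluation: stratified 10-fold cross-validation (group-aware when segment-
level samples share subjects), seeded and deterministic; if a split leaves a
training fold single-class it is re-seeded and logged. Confusion counts are
pooled over held-out folds (micro-average) — with a 77-subject cohort this
is the only aggregation under which the reported percentages are exact
rationals of the cohort size — and accuracy, sensitivity, specificity and
PPV (positive class = ASD) are computed in exact rational arithmetic before
rounding; zero-denominator ratios are NaN, never 0. The
accuracy-versus-number-of-features curve re-runs the CV with the top-m
ranked components, reporting the smallest m among ties.

## Synthetic cohort generator

No recordings ship with the package, so validation uses a generative
stand-in with a known ground truth. Each subject contributes `n_channels`
channels assembled from independent 512-sample epochs; per epoch and per
triplet (f1, f2) — defaults (8, 13), (6, 10), (11, 18) Hz, all with
f1 + f2 <= 40 Hz so the coupled component survives the band-pass — three
unit cosines at f1, f2, f1+f2 are added whose third phase is phi1 + phi2
with probability equal to the class's coupling strength (defaults 0.1 for
controls, 0.9 for cases) and uniform otherwise. Per-subject frequency jitter
(uniform, <= 1 Hz) creates inter-subject variability; 1/f background noise
(gamma = 1, a generic EEG-like spectral slope) is added at 10 dB SNR. The
epoch length equals the default bispectrum block length on purpose: phases
must decorrelate across analysis blocks, or an *uncoupled* triplet's triple
product would be constant across blocks and fail to average away, and the
two classes would be indistinguishable to any estimator. Class contrast is
encoded *only* in coupling probability — amplitudes and spectra are
identical — so the bispectrum stage is load-bearing: a pipeline that
dropped phase information would be at chance on these cohorts.

The generator emulates none of real ASD electrophysiology: no topography,
no artifacts, no inter-channel correlation, no non-stationarity beyond the
epoch structure. Passing end-to-end tests therefore demonstrates that the
chain detects phase-coupling contrasts of the stated size under 1/f noise —
not that it diagnoses autism.

### Problem sizes used in tests and the acceptance script

Cohort size is always 37 controls + 40 cases (one vector per subject).
The full-scale recording conditions the package models (64 channels, 20
minutes) are supported but unnecessary for validation; the shipped
experiments use desk scales chosen as the smallest that leave comfortable
statistical margin: 16 channels x 45 s (64 segment-images per subject) for
the strong-contrast run, 4 channels x 12 s for the null and monotonicity
runs, and 2-channel miniatures for unit tests. Per-subject feature variance
shrinks roughly with the number of averaged segment-images, so accuracy at
larger scales only improves.

## Known limitations

- The entropy-family definitions ("Kapur", "max", "Yager", "Vajda", log
  energy) are declared interpretations of ambiguous names; alternatives are
  config-swappable but untested against any external implementation.
- LSDA with d clamped to 18 cannot reproduce a 30-component reduction of an
  18-feature input; the reference-table regression therefore works from
  printed summary statistics, never from a refit.
- The t-test selection is uncorrected for multiplicity by design fidelity.
- EDF files can be read (via mne) but not written in this environment;
  cohorts persist as NPZ + CSV manifest.
- Bicoherence (normalised bispectrum) and higher HOS orders are out of
  scope; only the magnitude bispectrum is used.
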