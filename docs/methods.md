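# Methods

`seedspec` implements a complete VNIR (visible–near-infrared) hyperspectral
analysis pipeline for seed-accession identification, together with a
synthetic-data generator that stands in for a measured seed dataset so every
stage is testable end to end.

## Problem and data model

A push-broom VNIR camera images seeds arranged in a dish, yielding a raw
digital-number (DN) cube of shape lines × samples × bands. Relative
reflectance is obtained per pixel as

    R = (DN − dark) / (white − dark)

with dark-current and white-reference frames stored per band (a per-pixel
variant is a possible extension; the per-band default is a documented choice,
not an inference about any particular instrument). One seed contributes one
spectrum: the per-band mean over a 10 × 10-pixel region of interest (ROI)
fully inside the seed. The dataset is a matrix **X** ∈ R^(N×P) of N seed
spectra over P = 825 bands spanning 423.34–1022.07 nm (≈0.73 nm spacing),
with accession labels y ∈ {A01, …, A32}. The reference design is balanced:
32 accessions × 100 seeds, N = 3200.

ROI coordinates are 0-based with half-open `[top, top+height) ×
[left, left+width)` blocks. Cubes are serialized in the ENVI convention
(ASCII `.hdr` + flat little-endian binary; interleaves `bil`/`bip`/`bsq`;
data types uint16 and float32). Bands where white = dark are set to
reflectance 0 with a logged warning rather than raising, so one dead band
cannot abort a session.

## Preprocessing

The default chain is Savitzky–Golay smoothing (window 11, order 2) followed
by clipping to [0, 1]. Polynomial baseline correction (degree 2) and SNV
(standard normal variate) are implemented but off by default; when SNV is
enabled the [0, 1] clip is skipped because SNV output is a centered,
variance-normalized space, not reflectance.

Numerical choices:

* **SG edge handling.** Interior points use the standard centered
  least-squares convolution. Each edge point is the value at its own
  position of a polynomial fitted to the *truncated* window of available
  samples — no padding — so polynomials of degree ≤ the filter order are
  reproduced exactly everywhere, edges included.
* **SNV denominator.** Sample standard deviation (P − 1). The convention is
  recorded here because both conventions satisfy the same invariance
  properties; only the hand-checkable values differ.
* **Bandwise standardization.** μ_j uses 1/N, σ_j uses 1/(N − 1);
  zero-variance bands standardize to 0 and their indices are recorded. When
  used for modeling, the scaler is always fitted on training rows only.

## Exploratory statistics

* **PERMANOVA** on Euclidean distances with accession as the factor.
  Because the distance is Euclidean, the Anderson sum-of-squares
  decomposition reduces to the classical identities SS_total =
  Σ‖x_i − x̄‖², SS_within = Σ_g Σ_{i∈g} ‖x_i − x̄_g‖², and
  F = (SS_between/(g−1)) / (SS_within/(N−g)), which the implementation
  exploits so that 999 whole-label permutations at N = 3200, P = 825 run in
  seconds. The p-value uses the +1 correction, p = (1 + #{F_perm ≥ F_obs}) /
  (1 + n_perm), so it can never be zero. The test suite cross-checks the
  pseudo-F against scikit-bio's independent implementation and verifies
  type-I calibration (rejection rate 0.05 ± 0.02 under the null).
* **One-vs-rest association maps**: Pearson r between each band and the
  binary indicator of each accession. Degenerate cells (constant band or
  indicator) return r = 0 with a flag. The strongest association is reported
  with ties broken by lower wavelength, then lexicographic accession.
* **Hierarchical clustering** of accession-mean spectra under Euclidean
  distance, default UPGMA (average) linkage — standard for smooth spectral
  profiles and deterministic; the linkage is recorded in the result and
  switchable. Trees export to Newick.

## PCA

PCA consumes the bandwise-standardized matrix (raw-reflectance PCA exists
behind a flag for sensitivity checks only). Explained-variance ratios use
the sample covariance (1/(N−1)); component signs follow a deterministic
rule (largest-magnitude loading entry positive). scikit-learn's full SVD
solver does the decomposition; tests verify it against a brute-force
covariance eigendecomposition.

## ReliefF band ranking

ReliefF is implemented from scratch. For every training spectrum i (m = all
training rows, a fully deterministic pass), the k = 20 nearest *hits* (same
accession; k + 1 retrieved and the query itself excluded) and k = 20 nearest
*misses* (nearest rows of any other accession, pooled) are found by
Euclidean distance in the full 825-band space, and each band weight is
updated with raw absolute differences scaled by 1/(m·k):

    w_j ← w_j − (1/mk) Σ_{h∈H_i} |x_ij − x_hj| + (1/mk) Σ_{r∈M_i} |x_ij − x_rj|

Design decisions: misses are pooled across classes (k nearest of any
different accession), a documented divergence from the per-class
prior-weighted textbook variant; no max–min range normalization (reflectance
is already in [0, 1]); neighbor-distance ties break by ascending row index
and weight ties by ascending wavelength; classes smaller than k + 1 are
rejected rather than guessed at. The ranking is computed on the training
partition only — a provenance-tag guard rejects inputs containing test rows.
Tests require exact (1e-12) agreement with a nested-loop reference
implementation.

## Classification and evaluation

Stratified 80:20 hold-out (train 2560 / test 640 at the reference design;
20 test seeds per accession), with an optional validation subset (15% of
train = 384 rows, leaving 2176) drawn from the training side only. A
within-accession stratified 5-fold CV (20 test seeds per accession per
fold) probes robustness.

The baseline is a soft-margin linear SVM, one-vs-rest, C = 1.0 — the model
family is fixed and the hyperparameters logged since no canonical settings
exist. A registry adds k-NN, linear discriminant analysis, Gaussian naive
Bayes, and a shallow MLP as comparators; a 25-model benchmark is a non-goal.

All metrics derive from the confusion matrix C_ab: accuracy, error rate,
per-class precision/recall/F1, and support-weighted plus macro averages
(computed through a common path so they are *exactly* equal on balanced test
sets). Accession-level accuracy is the modal predicted label per accession
versus its true label, ties broken to the lexicographically smallest modal
label (a strict "tie = incorrect" policy is available by flag).

Uncertainty respects the nesting of seeds within accession lots:

* **Cluster bootstrap** (B = 1000, percentile interval): whole accessions
  resampled with replacement, their seeds' correctness flags pooled.
  Coverage is verified by simulation (95% intervals cover the true pooled
  accuracy in ≥ 90% of replicates with heterogeneous per-accession
  accuracies).
* **Exact Clopper–Pearson interval** for accession-level accuracy as a
  binomial proportion with 32 units (e.g. 32/32 → lower bound
  (α/2)^(1/32) ≈ 0.8911).

Micro-averaged ROC and PR curves binarize labels one-vs-rest and pool all
(sample, class) pairs; AUC by trapezoid, AP by the step-function definition
(no interpolation). Validation-curve tuning evaluates a parameter grid on an
internal validation split; the test set is never touched by model selection.

## Reduced-band study

Three reduction schemes, all evaluated under the same fixed hold-out split
with scaler and model refitted per selection: (i) the top K = 16
ReliefF-ranked wavelengths (training partition only), (ii) the green window
562.85–584.65 nm (closed interval, with half-print slack of 0.005 nm so a
band whose wavelength *prints* as the bound is included — on the study grid
this gives 31 bands), and (iii) uniform downsampling at steps of 5–30 nm
(defaults {5, 10, 15, 20, 25, 30}), each target wavelength mapped to the
nearest measured band with duplicates removed.

## Synthetic data: what it emulates and what it does not

Each accession archetype is a sigmoid visible→NIR transition near 700 nm
plus Gaussian absorption dips, bounded to [0.02, 0.98] — a minimal
parametric form reproducing the qualitative VNIR seed-reflectance shape.
Seeds deviate from their archetype by a per-seed multiplicative gain
(normal, mean 1, sd 0.03 — scattering/albedo variation), a per-seed additive
offset (sd 0.01), smooth wavelength-correlated noise (sd 0.008, correlation
length 50 nm), and iid sensor noise (sd 0.003), then clip to [0, 1]. The
magnitudes are calibration-free choices of plausible chemometric noise
scales, not estimates of any real seed lots; identical seeds give
bit-identical output.

Class geometry is controlled by presets:

* **easy** — accessions sit on a lattice of visible (spacing 0.06) and NIR
  plateau (spacing 0.13) reflectance levels plus accession-specific minor
  dips, guaranteeing every pair differs by > 0.05 somewhere; a linear
  classifier reaches ~100% test accuracy.
* **hard** — three designated accession pairs are near-duplicates (the twin
  adds a single dip of depth 0.003, max curve difference < 0.02,
  deliberately below the smooth-noise scale), so misclassifications
  concentrate reciprocally on those pairs while other accessions stay
  separable.
* **planted window** — all accessions share one base curve and differ only
  in the depth of a dip at the window midpoint (depths 0.06–0.50, width
  4 nm), so the window carries *all* class signal; this is the ground truth
  for band-ranking recovery and for the reduced-band ordering experiments.

Hypercubes render seeds as hard-edged disks (diameter 15 px ≥ 14) on a
background of reflectance 0.05, with DN = dark + R·(white − dark) + sensor
noise. Not emulated: seed texture and mottling, specular highlights,
partial-volume edge mixing, multi-dish session effects, instrument drift.
Passing tests therefore demonstrate the correctness of the *algorithms*
under a controlled forward model, not field performance on measured seeds.

## Problem sizes and determinism

The package's own verification experiments use: the full 32 × 100 × 825
design for end-to-end recovery, ReliefF window recovery, and the acceptance
script; N = 60 (3 × 20, 199 permutations, 500 replicates) for PERMANOVA
type-I calibration; N = 2000 for the ReliefF irrelevant-band null; 200
replicates × B = 1000 for bootstrap coverage. Every stochastic component
(generator, splits, permutations, bootstrap, reference subsampling) takes an
explicit integer seed, default 42; reruns with identical configuration are
bit-identical for the deterministic stages.

## Known limitations

* The synthetic noise model is stationary across wavelength and seeds; real
  instruments drift and real lots are heteroscedastic.
* PERMANOVA is implemented for Euclidean distances only (the decomposition
  used exploits that); non-Euclidean dissimilarities are out of scope.
* ReliefF rejects classes smaller than k + 1 instead of shrinking k; the
  balanced study design never triggers this.
* The ENVI reader supports the subset of the format the pipeline writes
  (little-endian, uint16/float32, per-band references in the header).
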