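# Methods

`fluorocold` reimplements an analysis chain for identifying cold stress in
plants from snapshot multispectral fluorescence images: demosaicing of a
5 × 5 multispectral-filter-array (MSFA) frame, dark correction, leaf-ROI
spectral extraction, PCA-residual quality control, SPXY calibration/prediction
splitting, four classifiers (LDA, QDA, Gaussian SVM, and a CNN–GRU sequence
network), confusion-matrix metrics with 10-fold cross-validation and Tukey
HSD, 1-D Grad-CAM wavelength attribution with ANOVA screening, and pixel-wise
classification maps.  Because the original pepper dataset is not publicly
deposited, a synthetic generator reproduces the statistical structure the
analysis assumes, and every stage is validated against independent oracles on
that synthetic data.

## Synthetic fluorescence model

Chlorophyll in leaves fluoresces in the red/far-red when excited by UV/blue
light, with emission maxima near 685 nm (F685) and 740 nm (F740).  The
generator's class template is the sum of two Gaussians at those positions
(default widths 18 and 35 nm) evaluated at 25 band centers, scaled by a
per-class amplitude.  Cold stress suppresses fluorescence yield, so the
amplitudes are strictly decreasing from normal to severe stress.

Parameters (units, defaults, rationale):

- `wavelengths`: 25 evenly spaced centers from 603 to 870 nm (step
  11.125 nm).  Only the camera's spectral range is public, not its exact
  band centers; an explicit list may be supplied.  Named bands (639, 679,
  693, 717, 757 nm) are mapped to the nearest grid point by
  `nearest_band`, which also reports the mismatch.
- `class_amplitudes` (intensity units): default (3.0, 2.2, 1.5) — ordered
  but overlapping once sample-level variability is added, emulating a
  moderately hard three-class problem.  The test benchmarks use the
  well-separated setting (3, 2, 1) with low noise where stated.
- `sample_cv` (unitless, default 0.25): coefficient of variation of a
  per-sample log-normal factor with mean exactly 1, emulating illumination
  non-uniformity and leaf geometry.  Multiplicative, because these effects
  scale the whole emission spectrum.
- `noise_sd` (intensity units, default 0.15): additive per-band Gaussian
  sensor noise.  Spectra are clipped at 0 (intensities are nonnegative);
  this adds a small positive bias to band means where the template is near
  zero, which the generator tests account for analytically.
- Saturation: a configurable fraction of scene pixels is forced to the
  16-bit sensor maximum before mosaicking, emulating clipped pixels.

What the generator does **not** emulate: radiometric camera response,
optics (blur, vignetting), spatial correlation of noise, leaf texture and
3-D canopy geometry, day-to-day drift.  Tests passing on synthetic data
demonstrate that the pipeline's computations are correct and that the
models can recover planted structure; they do not certify accuracy levels
on real plant data.

## Demosaicing and correction

The mosaic interleaves 25 bands in repeating 5 × 5 tiles.  Demosaicing is
pure subsampling: band *b* of spatial cell (i, j) is read from frame pixel
(offset_y + 5i + r_b, offset_x + 5j + c_b), where (r_b, c_b) is the tile
position of band *b*.  With the camera's offsets (x = 0, y = 3), a
2048 × 1088 frame yields 409 × 217 × 25 — the published geometry, which
fixes both the interpretation of "offsets along x and y" (column 0, row 3)
and the discarding of incomplete edge tiles.  The within-tile band layout
is not public; a row-major bijection is the default and is pinned by exact
mosaic/demosaic round-trip tests (any fixed bijection is equivalent
downstream).  Dark correction subtracts the dark-reference cube band-wise;
negative differences are floored at 0 (fluorescence is nonnegative — the
subtraction formula itself is silent on this).

ROI spectra are means over pixels whose centers fall inside a polygon under
the even–odd rule, which is vertex-order-invariant and reproducible; three
leaf ROIs per pot are averaged into one representative spectrum.

## Outlier screening (SPE/DModX)

A 2-component mean-centered PCA (the number of components follows the
two-PC projection used for screening; configurable) is fitted to all
spectra; each sample's squared prediction error (SPE) is the squared norm
of its residual off the component plane.  The "±2.5 standard deviations"
rule is implemented as the one-sided cut SPE > mean + 2.5·SD (SD with
N − 1): SPE is nonnegative, so a symmetric lower bound can never flag
anything.  Whether the original rule applied to raw SPE or a normalized
DModX variant is not stated; raw SPE is implemented and labeled as such.
Screening happens once, before splitting.

## SPXY splitting

D_x is the Euclidean distance between spectra, D_y = |y_i − y_j| between
numeric labels; D_SPXY = D_x/max D_x + D_y/max D_y ∈ [0, 2].  Selection is
the standard greedy max–min construction (the source describes only the
distance): seed with the farthest pair, repeatedly add the sample whose
minimum distance to the selected set is largest, until the calibration set
holds round(0.7·N) samples (half-up rounding; no rounding rule is given).
Ties break on the smallest sample id for determinism.  Selection is global,
not class-stratified, reproducing the acknowledged per-class imbalance of a
global splitter; a stratified variant and a seeded random split exist as
labeled alternatives.  Degenerate inputs (all spectra or all labels
identical) drop the degenerate term with a warning instead of dividing by
zero.

## Classifiers

LDA and QDA run at scikit-learn defaults.  The Gaussian (RBF) SVM accepts
(gamma, C) directly — e.g. an externally tuned pair such as
(6.98, 17.66) — or tunes them with a genetic algorithm maximizing mean
5-fold CV accuracy.  GA settings (population 20, generations 30, tournament
size 3, blend crossover and Gaussian mutation in log10 space, bounds
gamma ∈ [1e−3, 1e2], C ∈ [1e−2, 1e3], fully seeded) were not specified
upstream and are this package's choices, validated against a dense grid
search on analytic objectives.

The deep model treats the spectrum as an ordered sequence over wavelength:

| layer | output shape |
|---|---|
| input | (N, 25, 1) |
| Conv1D #1, 128 filters, kernel 2, stride 1, same padding, He-normal | (N, 25, 128) |
| Conv1D #2 + BatchNorm + ReLU | (N, 25, 128) |
| GRU encoder → final hidden state | (N, 64) |
| context vector = state repeated 25× | (N, 25, 64) |
| GRU decoder → final hidden state | (N, 64) |
| Dense 64 + ReLU | (N, 64) |
| Dense (32 default / 64 variant) | (N, ·) |
| Dense 3 + softmax | (N, 3) |

Design notes where the source is ambiguous or silent:

- The prose says the MLP head has 64 and 32 neurons while the layer table
  prints 64/64; both heads are built, default (64, 32), table variant by
  flag.  Neither is "resolved" — the discrepancy is surfaced.
- ReLU follows Dense #1 only by default ("ReLU throughout prior to
  softmax" is ambiguous); a flag adds it after Dense #2.
- Conv #1 has no activation: batch norm + ReLU attach to Conv #2 only, as
  in the layer table.
- The context vector is the encoder's final state repeated 25 times
  (matching the (N, 25, 64) context shape); the decoder returns its final
  state only (matching (N, 64)).
- GRU convention: classic reset-before-matmul gates
  (h̃ = tanh(xW + (r∘h)U + b), h′ = z∘h + (1−z)∘h̃), Glorot kernels,
  orthogonal recurrent kernels, zero biases; parameter count per GRU is
  3(nm + n² + n).
- 'same' padding with the even kernel 2 puts the single extra zero on the
  right.

The network and its reverse-mode gradients are implemented directly in
NumPy (`fluorocold.nn`): exact analytic backprop through the convolutions,
batch norm, both GRUs and the dense head, verified against central finite
differences in the test suite.  Exact gradients are also what 1-D Grad-CAM
consumes.  Training: Adam, categorical cross-entropy on one-hot labels,
batch 8, initial learning rate 3e−4, at most 500 epochs, early stopping on
validation loss (min delta 1e−4, patience 50, best weights restored),
learning-rate halving on a 25-epoch plateau, stratified 4:1
train/validation split at seed 42.  All randomness flows from one seed, so
training is bit-reproducible run to run on the same platform.

## Evaluation

Metrics come from the 3 × 3 confusion matrix by one-vs-rest reduction and
the printed formulas: per-class balanced accuracy ((sens + spec)/2 × 100),
precision, recall, and F1, aggregated as support-weighted means on the
0–100 scale.  The balanced-accuracy formula is a binary definition applied
per class and support-weighted — the reduction is this package's documented
reading of a binary formula used in a multiclass setting.  Weighted recall
algebraically equals the plain fraction correct, which the tests assert.
Division by zero (a class never predicted) yields 0 with a warning.
One-vs-rest ROC/AUC uses trapezoidal integration.  Cross-validation is
stratified k-fold (default 10) with per-fold refitting; fold accuracies per
model, computed on a shared fold partition, feed Tukey's HSD (studentized
range; scipy's implementation) for pairwise model comparison.  The
"calibration" column of reported metrics is resubstitution on the
calibration set, labeled as such.

## Interpretation

Grad-CAM for spectra: for a target class, the gradient of that class's
logit with respect to the last convolutional feature map (the
BN + ReLU output of Conv #2 — the canonical "last conv layer", and the only
conv stack present) is averaged over the 25 sequence positions into one
weight per channel; the per-position score is the ReLU of the
channel-weighted feature sum.  The sequence length already equals the band
count, so no upsampling is involved.  Profiles are computed on correctly
predicted samples, each attributed against its true class; per-band one-way
ANOVA across the three class groups of per-sample scores (the only variant
with degrees of freedom, and labeled as such) flags bands at p < 0.05, with
no multiple-testing correction by default (a Bonferroni flag exists).

Localization is only defined up to the last conv layer's receptive field:
two stacked kernel-2 convolutions make each feature position depend on
itself and the next two bands, so an attribution peak can sit up to two
positions left of the truly informative wavelength.

Classification maps score every pixel's spectrum with a trained model and
write the argmax class; pixels with mean intensity below a configurable
floor (default 0 = no masking) are background (−1).  Pixel spectra are
noisier than the leaf-averaged spectra used in training, so map accuracy
inherits and typically slightly trails model accuracy — the tests assert
the resulting monotone degradation with noise.

## Numerical choices and problem sizes

Desk-scale experiment sizes used by the test suite (package choices):
well-separated benchmark 300 spectra/class (seed 7) with a 60-epoch budget;
permuted-label control 150/class with the full 500-epoch budget (early
stopping terminates it quickly); 10-fold CV and the 20-replicate
Grad-CAM band-recovery screen use 100/class with a 25-epoch budget; the QC
bookkeeping benchmark uses 2385 spectra with planted off-plane corruptions.
Tolerances are stated per experiment in the tests (e.g. mean spectra within
2% of the analytic clipped mean at n = 1000; chance-level accuracy
33.3 ± 5 points).

## Known limitations

- The deep network runs on a single CPU in NumPy; it is sized for 25-band
  spectra, not large images, and there is no GPU path.
- SVC class probabilities come from Platt scaling, which can disagree with
  the raw SVM decision on degenerate kernels (e.g. extremely large gamma on
  mismatched feature scales); argmax-of-probability is used uniformly for
  all models.
- The SPE threshold assumes a roughly unimodal SPE distribution; masking
  can occur if a few extreme, collinear outliers dominate the PCA itself.
- Global SPXY splitting is deterministic but O(N²) in memory for the
  distance matrix.
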