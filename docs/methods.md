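# Methods

This package implements a two-track classification pipeline for ATR-FTIR
spectra of three *Ganoderma* species (*G. lucidum* = GL, *G. sinense* = GS,
*G. tsugae* = GT): a chemometric track (PCA, PCA-class/SIMCA, OPLS-DA with a
validation battery) and a deep-learning track (SMOTE balancing, a 1-D CNN
under stratified 10-fold cross-validation, and a repeated random-segregation
robustness protocol).  This note records the models, the defaults and why,
and the design choices that were genuinely open.

## Synthetic spectra generator

Real spectra of the three species are near-identical: twelve shared
absorption bands between 3310 and 880 cm⁻¹ whose positions differ by only
0–12 cm⁻¹ across species, the largest contrast being the β-anomeric
saccharide band at 892 cm⁻¹ (GL, GS) versus 880 cm⁻¹ (GT).  The generator
emulates exactly this structure on the instrument grid (4000→400 cm⁻¹,
1 cm⁻¹ interval, stored descending):

* each spectrum is a sum of Gaussian bands (centers per species from the
  twelve-band library), plus a random polynomial baseline, plus additive
  white noise;
* per-sample variation: band amplitude `base_amplitude·(1 + cv·z)` with
  `cv = 0.15`, and center jitter `N(0, 1.5 cm⁻¹)`;
* strong bands (O–H stretch 3310, C–H stretch 2920, and the C–O saccharide
  bands 1067/1039 cm⁻¹) get base amplitude 1.0, the others 0.4 absorbance
  units; band FWHMs range from 220 cm⁻¹ (the broad O–H stretch) to 20 cm⁻¹
  (the sharp anomeric band);
* baseline: order-2 polynomial with coefficients uniform within ±10% of the
  maximum band amplitude — the smooth drift the preprocessing chain removes;
* noise: `N(0, 0.005)` absorbance per point;
* default class sizes 78/20/20 (GL/GS/GT), the composition of the original
  sample set.

Band shape is Gaussian; Lorentzian/Voigt shapes, water-vapour/CO₂ artifact
bands and instrument-resolution convolution are deliberately not modelled —
the generator reproduces the *classification structure* of the data, not the
physics.  The within-class variance of the real samples is unknown, so the
jitter/amplitude defaults are plausible placeholders, chosen once; passing
recovery tests therefore demonstrates that the pipeline recovers structure
of this kind and strength, not that it would reach the same numbers on real
fruiting-body spectra.

## Preprocessing chain

Fixed order ATR → baseline → smoothing → subtraction/normalization, each step
per spectrum (no information crosses samples):

* **ATR correction** — absorbance scaled by ν/ν_ref (ν_ref = 1000 cm⁻¹), the
  first-order compensation for the 1/ν dependence of evanescent-wave
  penetration depth.
* **Baseline** — asymmetric least squares (AsLS), smoothness λ = 1e6,
  asymmetry p = 0.01, 10 reweighting iterations, solved per spectrum with a
  banded Cholesky factorization.  λ = 1e6 keeps the baseline from climbing
  into bands of realistic width: at 1 cm⁻¹ spacing, λ = 1e5 costs a 40 cm⁻¹
  band about 7% of its height, λ = 1e6 about 2%.
* **Smoothing** — Savitzky–Golay, window 11 points, polynomial order 3
  (exact on cubic signal, reduces white-noise variance).
* **Subtraction/normalization** — subtract the per-spectrum minimum, divide
  by the new maximum (range exactly [0, 1]); a zero-mean unit-norm vector
  mode is available as an alternative.

All steps can be disabled individually for ablations.  The vendor software
used for the original measurements is proprietary, so numerical equality
with its output is not claimed anywhere.

## Chemometric track

Spectra are split 60/40 into calibration and validation, stratified by class
(per-class calibration count = round(0.6·n), ties up: 78/20/20 → 47/12/12).

**PCA** is computed by NIPALS with deflation (scores/loadings match the SVD
solution up to sign; the equivalence is tested at 1e−6).  Cumulative Q² uses
venetian-blind cross-validation (default 7 folds, the convention of the
chemometric software family this mirrors): per fold, a PCA fitted on the
remainder reconstructs the held-out spectra; Q² = 1 − PRESS/SS.

**PCA-class (SIMCA)** fits one PCA per class (mean-centered within class,
equal component count per class, default 2) and measures membership by the
normalized distance to the model, DModX = s_i/s₀ with
s_i² = Σe²/(p−a) and s₀² = ΣΣe²/((n−a−1)(p−a)).  The critical limit is a
moment-matched scaled chi-square quantile of the squared distances
(Nomikos–MacGregor): the classical F-quantile with p−a nominal degrees of
freedom assumes independent residuals across wavelengths, and structured
spectral residuals violate that badly (observed calibration coverage 72–84%
instead of 95%); moment matching restores close-to-nominal coverage.  Forced
single-label assignment is argmin DModX; equal component counts across
classes keep those distances comparable (a per-class Q² autofit was tried
and rejected — the most-fitted submodel becomes an attractor).

**OPLS-DA** encodes classes as a one-hot dummy matrix Y (mean-centered,
X mean-centered only by default; unit-variance and Pareto scaling are
options).  Variation orthogonal to Y is removed component by component: an
orthonormal basis V of span(XᵀY) is computed, one PLS2 component is fitted,
its X-loading is projected off V, and the resulting orthogonal component is
deflated out; a PLS2 model with K−1 predictive components is then fitted on
the filtered X.  Orthogonal components are accepted while cross-validated
Q²Y improves by more than 0.01, up to 5.  Predictive and orthogonal score
blocks are exactly uncorrelated on training data, and R²X(predictive) +
R²X(orthogonal) + residual fraction = 1 to numerical precision (both are
tested).  Classification of new spectra applies the training orthogonal
filter, projects, and takes argmax of the predicted dummies, so every
spectrum receives exactly one label.

Error measures follow the estimation/cross-validation/prediction convention:
RMSEE divides the squared residual sum by (N−1−a)·K with a = total fitted
components, RMSECV and RMSEP divide by N·K.

The **permutation test** (default 100 permutations) refits the model with
the same component structure on uniformly permuted labels, records R²Y and
Q²Y against the absolute correlation between permuted and original centered
dummy matrices, and reports the least-squares line intercepts at zero
correlation (the unpermuted reference at correlation 1 is included in the
fit).

## Deep-learning track

The raw class imbalance (78/20/20) is handled exactly as in the original
design: a stratified, mutually exclusive half-split into group A (training)
and group B (testing), then SMOTE oversampling of every class *in both
groups independently* to 500 samples per class (1500 per group).  Each
synthetic sample lies on the segment between an original and one of its
k = 5 nearest same-class, same-group neighbours (k capped at class size −1);
neighbour search never crosses groups or classes, and per-(group, class)
sub-seeds make group B's synthesis independent of group A's content.
Oversampling the *test* group is methodologically unusual but faithful to
the original protocol; `balance_groups(..., oversample_test=False)` provides
the conventional alternative.  SMOTE runs on preprocessed spectra, since the
CNN consumes the preprocessed curves.

The classifier is a small 1-D CNN written directly in NumPy (im2col
convolutions with explicit backward passes): two convolution + max-pooling
blocks, a dense rectifier layer and a softmax output, trained with Adam
(learning rate 1e−3, batch 32) on categorical cross-entropy, with early
stopping on validation loss (patience 10) and per-fold weight
re-initialization.  The default preset is conv(16 filters, kernel 7) →
pool 4 → conv(32, kernel 5) → pool 4 → dense 32 → softmax, applied to
spectra downsampled to every 2nd grid point by default.  These sizes are
this package's own choices, made for single-CPU training times; every field
of the architecture and the training configuration is exposed.  All
randomness (initialization, batch shuffling, dropout) funnels through one
seed, giving bit-identical fold metrics across runs on the same machine in
single-threaded mode.

Model selection uses stratified 10-fold cross-validation on group A
(per-class fold counts differ by at most one; 500/500/500 → 50/50/50 per
fold).  The **random segregation test** evaluates each of the 10
fold-trained models on all of group B (10 repetitions), recording one
confusion matrix per repetition; an alternative mode retrains a fresh model
per repetition.

## Evaluation conventions

Confusion matrices are oriented rows = predicted, columns = true (a
transpose accessor is provided).  Accuracy, sensitivity and specificity are
micro-averages from one-vs-rest TP/TN/FP/FN counts pooled over classes —
for K classes these satisfy the exact identities acc = 1 − 2e/K and
spec = 1 − e/(K−1) with e = 1 − sens, which the test suite verifies on every
matrix and on the reported result tables.  Precision, recall and F1 are
macro-averages of per-class values (classes with empty denominators
contribute 0 with a warning).  Run summaries report the mean, the
*population* standard deviation (divisor n — the convention that reproduces
the reported summary row exactly) and CV = 100·sd/mean.

## Problem sizes used by the test suite

The acceptance-style tests run the full pipeline at the study's sample sizes
(118 spectra, SMOTE to 1500 per group) with the CNN on an every-4th-point
grid (901 features) and up to 15 epochs per fold; chemometric recovery is
averaged over five generator seeds.  Unit tests use a 251-point grid and
28–100-sample datasets.

## Known limitations

* The generator's within-class variance is a placeholder; recovery
  thresholds characterize the pipeline, not the real samples.
* The AsLS/Savitzky–Golay/min-max parameterization is one reasonable
  realization of a preprocessing chain described only qualitatively in the
  original protocol.
* The SIMCA membership limit targets nominal coverage through moment
  matching; it is an approximation, and per-class distances remain sensitive
  to small calibration sets (12 samples per minority class).
* The CNN architecture details of the original study are not public; the
  preset here is not a reconstruction of them.
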