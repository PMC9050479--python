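# Methods

This note records the models, parameter choices and numerical decisions
behind `hsinuclei`, and what the simulation-based tests do and do not
establish about real data.

## Transmittance calibration

Raw detector counts are converted per pixel and band to
`T = (I_raw − I_dark)/(I_white − I_dark)`. The transform is invariant to
any affine rescaling of the detector response, which the tests verify
directly. Two numerical choices:

- **Clipping.** Noise pushes blank-region transmittance slightly above 1;
  values are kept up to `clip_max = 1.5` and clipped there. Hard clipping
  at 1.0 would bias blank-region statistics downward.
- **Degenerate denominators.** Pixels where white and dark coincide at
  any band carry no information; they are flagged in a 2-D validity mask
  (stored as a JSON sidecar next to the ENVI pair) rather than set to
  NaN, so downstream stages can skip them without NaN propagation.

ENVI I/O is implemented in the package (header + BSQ/BIL/BIP binary,
wavelengths assumed nm when unlabeled); round-trips are bit-exact for
integer cubes.

## Registration

One affine transform per imaging session is estimated from a
calibration-target pair: ORB keypoints in both grayscale frames, binary
descriptor matching with cross-check, RANSAC (reprojection threshold
3 px, ≥ 50 features required per image) fitting the affine model. RGB
grayscale uses 0.299/0.587/0.114 luminance weights; a hyperspectral cube
is reduced by its band mean. Per-image re-registration is possible but
off by default — the two cameras are rigidly mounted, so one transform
serves the session. The margin mask is computed analytically as the set
of output pixels whose preimage leaves the moving frame, not from
interpolation artifacts. On synthetic targets the estimator recovers
translations ≤ 20 px, rotations ≤ 5° and scales 0.95–1.05 to well under
0.5 px mean interior error; no claim is made about residual error at the
edges of real optics.

## Display RGB synthesis

Channel weights are raised-cosine lobes evaluated at the band centers:
blue centered 450 nm (half-width 100 nm, so support reaches 550 nm),
green 550/60, red 600/80 plus an auxiliary red lobe 440/60 at amplitude
0.25 and a 1.08× boost of red weights over 500–720 nm (halogen sources
are red-heavy). Each channel is renormalized to unit sum so a blank
slide renders neutral; the weighted sums are doubled for brightness and
clipped to [0, 1]. The lobe parameters are display choices, not
colorimetry, and are all overridable; if a channel's lobe support misses
every available band, its mass falls back to an exponential decay from
the lobe center so the nearest bands carry it.

## Nuclei segmentation

PCA is computed over pixels-as-samples and bands-as-variables via the
87×87 band covariance (eigendecomposition; identical to an SVD-based PCA
to 1e-8, which a test checks against an independent implementation).
Because eigenvector signs are arbitrary, orientation is restored from
the data: all four sign combinations of (PC1, PC2) are evaluated and the
one whose difference image `PC2_norm − PC1_norm` calls a *minority* of
pixels positive with the *darkest* positive set (nuclei are
hematoxylin-dense, hence dark) is selected. Exhaustive search makes the
final mask exactly invariant to input sign flips; an exact tie falls to
the orientation with the higher mean boundary gradient.

Numerical parameters:

- **Threshold 0** on the difference image (strict `>`), following the
  sign convention of the difference image.
- **`min_area` 200 px** at 139 nm/px. Lymphocytes (the simulator renders
  them at radius 3–6 px, area < 115 px) and debris fall below this floor;
  the recovery tests assert they are never detected.
- **Watershed**: seeds are local maxima of the distance transform,
  smoothed with a Gaussian of σ 2 px, at least 10 px apart; the watershed
  floods the inverted (unsmoothed) distance map. A 5-px seed separation
  was tried first and over-splits elongated nuclei whose distance ridges
  carry several maxima; 10 px with smoothing splits discs 1.2 radii
  apart while leaving single nuclei untouched. Fragments below
  `min_area` after splitting are dropped.
- **Out-of-focus nuclei** receive no special handling; an optional
  variance-of-Laplacian focus filter exists but is off by default.

Patches are 101×101, centered on the rounded centroid; windows leaving
the frame or touching the registration margin are dropped.

## Spectra-based SVM

Nucleus spectra are mask-mean transmittance, sum-normalized
(`SN = S/ΣS`), which removes thickness/staining amplitude but not
shape changes (thickness enters Beer–Lambert as a power of T, so only
the first-order amplitude effect cancels). The classifier is an RBF-SVM
grid-searched over log2 C, log2 γ ∈ {−1…4} (36 pairs). Two decisions:

- **Per-band standardization before the kernel**, fit on the training
  partition only. Sum-normalized 87-band spectra live at ~1/87
  amplitude, where squared distances are ~1e-6 and the entire γ grid
  degenerates to a constant kernel; standardization restores the grid's
  leverage. This is an implementation detail of the classifier, not a
  change to the normalization itself.
- **Inner model selection** uses stratified 5-fold CV accuracy within
  each LOPO training partition; ties break toward smaller C, then
  smaller γ (the simpler model).

Leave-one-patient-out CV guarantees no record of the held-out patient
influences training; a property test checks fold assignment is
order-invariant.

## Patch CNN

The architecture follows the published table: convolutions
(5,3,3,3,3,3,3,3,3 kernels; 256, 256, |pool|, 384, 512, 768, |pool|,
768, 1024, 1536, 2048 filters; stride 1, valid padding), global average
pool over the final 13×13 maps, a 2048-unit ReLU dense layer, sigmoid
scalar output; ReLU + dropout (0.10 rising linearly to 0.30) after each
convolution. Two printed inconsistencies are resolved as follows: the
second max-pool's channel count is kept at its input's 768 (pooling
cannot change channels), and since 2/2 valid pooling maps 95→47 but
41→20, the second pool runs in ceil mode (pad-and-pool, 41→21) so the
printed spatial chain 101→97→95→47→45→43→41→21→19→17→15→13 holds
exactly — a test asserts every entry for both N = 3 and N = 87.

Defaults follow the full-scale training protocol: Adam (lr 1e-5, β₁ 0.9,
β₂ 0.999), binary cross-entropy, batch 16, ≤ 27 epochs with early
stopping on validation accuracy, Glorot-normal init, 4× rotation
augmentation in training and mean probability over four views (identity,
90° rotation, horizontal/vertical reflection) at evaluation. The
evaluation quartet is one admissible reading of "rotating and
reflecting" and is fixed in config.

**Desk-scale training.** The engine is plain numpy (per-offset GEMM
convolutions, float32), so tests and the acceptance script run the
architecture at `width_multiplier = 1/32` on one CPU. Three numerical
adaptations are required at that width, all config-exposed and none
affecting the full-width default: He-normal init (Glorot+ReLU attenuates
the forward signal ~0.6× per layer, which 256-wide layers tolerate but
8-wide layers do not), per-channel input standardization with
training-set statistics (raw all-positive patches let the optimizer
drive the first convolution's ReLUs dead — observed directly as the dead
fraction reaching 1.0 within 30 steps), and a learning rate of 1e-3
matched to the ~10² gradient steps of a desk-scale run rather than the
~10⁴ of the published protocol.

Patient-level leakage between train and validation partitions is a hard
error, and two runs with the same seed produce identical histories.

## Image-wise classification

A field is cancerous when the cancer-called fraction is **≥** the
threshold (inclusive; the source protocol says "above" without
specifying strictness, and inclusive keeps the boundary cases on the
sensitive side). Zero-nucleus fields are *indeterminate* rather than
normal. The threshold is selected from {1, 5, 10, 20, 30}% by maximizing
correct validation images, ties toward the smaller candidate because a
larger threshold trades false positives for the costlier false
negatives. ROC AUC uses the rank-statistic (Mann–Whitney) definition,
which handles score ties by midranks.

## The simulator

Scenes are Beer–Lambert (base-10) renderings: absorbance
`A = thickness · (c_hem · hem(λ) + c_eos · eos(λ))` with Gaussian
unit-peak stain curves (eosin 525/40 nm, hematoxylin 600/60 nm — the
peak positions are parameters, not measured values), `T = 10^(−A)`.
Nuclei are rotated ellipses with high hematoxylin; cytoplasm carries a
smooth eosin texture; a smooth-field blank region provides the
background phase PCA expects; small hematoxylin-rich discs emulate
lymphocytes. Raw cubes are `dark + T·(white − dark)` plus Gaussian shot
noise (σ = 1% of dynamic range), with a spectrally ramped white
reference; calibrating a generated cube against its own references
recovers the truth to within the noise, closing the loop on the
calibration equation.

The class difference is a multiplicative spectral tilt
`1 ± a·tanh((645 − λ)/25)` on nucleus spectra — cancerous transmittance
above normal below the 645 nm crossover and below it beyond, so the
class-mean spectra cross exactly once between 640 and 650 nm (tested).
Default amplitude `a = 0.035` emulates the subtle separation of real
cohorts; "strong separation" runs use 0.08. Per-patient staining and
thickness multipliers are lognormal (σ 0.15 and 0.2), drawn once per
patient; a configurable fraction of patients carries a *reversed* tilt,
modeling the empirically observed reversed-trend patients as a free
flag, since no mechanism for it is known. Setting the tilt to zero and
equalizing morphology yields the null simulator, under which the SVM's
LOPO accuracy is statistically indistinguishable from 0.5.

Two scales are used deliberately. Whole scenes render nuclei at radius
12–16 px so that fields of 30–150 non-touching nuclei stay affordable;
patch-level datasets render nuclei at the realistic nucleus-to-patch
ratio (radius 24–30 px in a 101-px patch — the patch size exists to
contain enlarged SCC nuclei). With scene-scale nuclei the spectral class
signal occupies ~4% of a patch and is swamped by patient-level variation
regardless of classifier, so the patch scale is the faithful condition
for classifier comparisons.

Problem sizes in the tests and acceptance script — 20 scenes for
segmentation recovery, 6 patients × 40 nuclei for the SVM study,
6 patients × 20 patches for the CNN comparison at width 1/32, 1000
simulated images for the error-propagation check — are the package's
desk-scale study conditions.

## What passing tests do and do not show

The simulator encodes the statistical structure the classifiers assume:
elliptical hematoxylin-rich nuclei, a single spectral crossover,
patient-level amplitude variation, shot noise, occasional defocus. It
does not model chromatic aberration, stage drift, focus gradients,
nuclear texture (chromatin patterns), overlapping tissue layers, or the
unexplained biology behind reversed-trend patients. Recovery results
therefore validate the implementation — that each stage does what it
claims under known generating conditions — not clinical performance.
The published per-patient results on the original 26 slides are not
reproducible here because those data are not deposited.

## Known limitations

- The SVM consumes segmentation masks; the original workflow hand-drew
  nucleus margins for spectra. `mean_nucleus_spectrum` accepts any
  externally supplied mask, so hand-drawn margins can be dropped in, but
  the automated path is the tested one and the gap is acknowledged.
- Nuclear boundaries from the difference-image mask are approximate; the
  mask locates nuclei for patch extraction, it does not delineate them.
- The numpy CNN engine is single-threaded BLAS-bound; full-width
  (multiplier 1.0) training is only practical on the original GPU-scale
  infrastructure, and the package treats it as a configuration rather
  than a tested path.
- PC3 is computed and retained (it highlights the background phase) but
  unused by the segmentation formula.
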