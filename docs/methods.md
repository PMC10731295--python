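# Methods

This note records the model assumptions, parameter choices, and known
limitations of `mycospec`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Imaging model and calibration

A transmittance micro-hyperspectral cube is modeled as

    I_raw(x, y, λ) = I_dark(x, y, λ) + T(x, y, λ) · (I_ref − I_dark) + ε,

where `T` is the dimensionless transmittance field and `ε` Gaussian
sensor noise (expressed in transmittance units and scaled by the local
gain). Black/white correction inverts this model exactly:
`R = (I_raw − I_dark)/(I_ref − I_dark)`. Cells where
`|I_ref − I_dark| < ε₀` (default `ε₀ = 1e−6`) are zeroed and counted; a
reference pair with more than 1 % degenerate cells is rejected. Because
noise and specimen brightness can push `R` past 1, the output is floored
at 0 and ceiled at a configurable `clip_max = 2`.

**Band window.** The instrument's reddest bands are noise-dominated. On
the package's uniform 401–1046 nm, 360-band axis the default crop keeps
336 bands *by count*, starting at the first band ≥ 400 nm (i.e. it drops
the 24 reddest bands, ending near 1003 nm). A pure inclusive wavelength
window is available as `crop_bands(low, high)`; the count-based default
was chosen because the effective-band convention is about discarding a
fixed detector tail, not about a physical 1000 nm boundary (real
spectrometer axes are slightly non-uniform, so a nominal "400–1000 nm,
336 bands" description does not pin down one uniform-axis window).

## Synthetic scenes

The generator emulates the study conditions the analysis assumes, one
cube per sample:

* **Filaments** are jointed random walks (1 px steps, heading increments
  N(0, 0.18) rad) grown in both directions from a random interior point,
  rasterized with a Gaussian cross-profile whose FWHM is the filament
  width; 3–6 filaments per 128×128 image. Coverage blends the mycelium
  and background endmember spectra linearly. The ROI mask is
  `coverage > 0.5` (≥ 50 px guaranteed).
* **Grades 0–3** (healthy → degraded) are encoded monotonically:
  filament width means 12 / 8 / 7.4 / 4.5 px (sd ≈ 1) strictly decrease;
  mycelium transmittance offsets 0 / 0.006 / 0.035 / 0.042 strictly
  increase ("narrower and slightly more translucent").
* **Spectral shapes.** All grades share one smooth background and
  mycelium curve family (sums of Gaussian peaks/valleys on a sloped
  baseline), so class spectra have similar trends. On top of the shared
  shape each grade modulates the mycelium peak/valley amplitudes by a
  small label-scaled term (weights 0 / 0.07 / 0.55 / 0.62 on ±0.03
  bumps). This mirrors the observation that in real data the mild grades
  differ from the strong grades in peak/valley shape while neighbours
  inside each group look alike — and it is what makes the spectral
  channel informative *after* SNV, which annihilates any purely constant
  offset. Widths do the opposite (0↔1 and 2↔3 well separated, 1↔2
  barely), so the spectral and image channels are complementary by
  construction.
* **Within-class variability.** Each sample perturbs its mycelium curve
  with four smooth random bumps (amplitude sd 0.01). Without this,
  ROI-mean spectra are essentially noise-free (they average thousands of
  pixels) and any systematic class difference would be trivially
  separable.
* **Distortions and noise.** Per *sample* (not per pixel): a
  multiplicative scatter slope `1 + N(0, 0.05)` and an additive baseline
  `N(0, 0.02)` — exactly the affine family that MSC inverts and SNV is
  invariant to. Per pixel-band: Gaussian sensor noise sd 0.008
  (transmittance units). Reference frames carry a smooth spectral
  illumination tilt and spatial gain at ±5 %.
* **Determinism.** All randomness flows from explicit seeds
  (`numpy.random.default_rng`); per-sample seeds derive from the master
  seed via `SeedSequence`. No global random state is touched.
* `class_contrast` scales every between-class difference; 0 yields
  statistically identical grades (a vanishing ordered residual keeps the
  monotone-encoding validation satisfied) for null experiments.

What the generator does **not** model: real mycelium branching
morphology, optics/PSF blur, per-pixel scatter, wavelength-dependent
noise, instrument axis non-uniformity, or dish-level spatial layout.
Passing tests therefore demonstrate correctness of the *algorithms* and
the qualitative orderings under the stated assumptions, not performance
on real cubes.

## Pretreatment conventions

* SNV uses the sample (n−1) standard deviation; constant spectra are
  errors. SNV output is exactly mean-0 / sd-1 and is invariant to
  positive affine transforms of its input.
* MSC fits `x ≈ a + b·ref` by OLS per spectrum and returns `(x − a)/b`;
  `|b| < 1e−8` is an error. The reference defaults to the mean spectrum
  of the matrix it is fitted on; in train/test workflows the training
  reference is reused for test spectra (no leakage).
* Savitzky–Golay defaults to window 11, polyorder 2 (a common
  chemometrics choice at ~1.8 nm sampling); edges evaluate the
  polynomial fitted to the nearest full window (`mode="interp"`).
* The pipeline's default pretreatment is SNV, which the pretreatment
  comparison grid supports empirically; it is a config choice.

## Band selection

`spa_chain` implements the successive projections recursion literally:
sequential deflation against the last selected *projected* column, which
composes to projection onto the orthogonal complement of all selected
columns (verified against an explicit pseudoinverse-projector oracle).
Norm ties break to the lowest band index; chains are bit-reproducible.
Numerical guards: all-zero columns are rejected; if every remaining
projected norm falls below 1e−12 the error reports the achievable chain
length.

The regression behind the RMSE curve is ordinary least squares of the
integer grade on the selected bands (plus intercept) under seeded k-fold
CV (default k = 5) — the simplest model consistent with SPA's
multiple-linear-regression motivation. All start bands are swept by
default (an integer `starts` draws a seeded subsample for speed); the
minimum-RMSE (N, start) wins, ties toward smaller N then smaller start.
Selection is fitted on the training partition only.

## Image features

Band images are center-cropped to the largest square, resized by
bilinear interpolation with pixel-center mapping (default 224×224),
min–max normalized per image (constant → zeros), and replicated to three
channels. The default backend is a deterministic seeded
random-convolution stack: three 3×3 convolution stages
(3→16→32→128 channels) with modulus nonlinearity and 2×2 mean pooling
between stages. Since filament *position* carries no grade information,
each stage is reduced to translation-invariant channel statistics
(global mean and sd per response map, 352 values) which a fixed seeded
linear map lifts to the 2048-d output; a spatial-grid pooling variant
was rejected because it encodes the random filament positions and
generalizes poorly. Per-sample vectors over the selected bands are
mean-pooled (max is available). The pretrained-ResNet50 backend
(pre-fully-connected pooled activations, also 2048-d) is optional and
requires torch/torchvision; without them it raises an error that points
to the seeded backend.

## Fused-kernel SVM

Features of each modality are z-scored with training statistics before
the RBF kernel. The fused training kernel is checked for symmetry and
positive semidefiniteness (tolerance 1e−8 on the minimum eigenvalue,
relative to the kernel scale), the dual solution for box and equality
feasibility (`0 ≤ α ≤ C`, `Σ α y = 0` per one-vs-one subproblem, 1e−6).
Grid search uses stratified k-fold CV (default 3 folds in the pipeline);
scalers and `"scale"` gammas (`1/(d·var)`) are resolved inside each
training fold. Accuracy ties break toward smaller C, then larger μ, then
smaller widths, making the selected configuration deterministic. With
μ = 1 (μ = 0) the fused kernel is bitwise the spectral (image) Gram
matrix, so single-modality baselines are endpoints of the same code
path.

## Partitioning and reporting

Kennard–Stone runs per class (stratified default) on SNV-transformed
spectra; the selected max–min points form the training set at a 4:1
ratio. Both modes (stratified/global) exist because the convention is
not fixed by the problem; stratified guarantees every grade in both
partitions. KS is fully deterministic, ties to the lowest index.
Per-class TP/TN/FP/FN are one-vs-rest collapses of the multiclass
confusion matrix; micro-averaged accuracy equals trace/total exactly.

## Problem sizes

Desk scale (the acceptance script and the generator defaults) is
4 grades × 30 cubes of 128×128 px × 360 bands — a full run takes a few
minutes on one CPU. The test suite exercises the same code paths at
smaller sizes (48–64 px, 40–100 bands, 12–15 samples per grade, images
resized to 48–64) chosen so the whole suite stays fast while every
property remains measurable. At desk scale the KS split concentrates
extreme samples in the training set, so test accuracies of the stronger
models can saturate at 100 % — the synthetic task at that size is easier
than the real one; the qualitative orderings (pretreatment ≥ raw,
feature extraction ≥ raw inputs, fusion ≥ single modality) are the
meaningful outputs.

## Known limitations

* Random-convolution features are a generic texture descriptor; they are
  weaker than a pretrained network on real imagery.
* The RMSE regression treats the ordinal grade as numeric; rank-based
  alternatives are out of scope.
* MSC/SNV correct the generator's per-sample affine distortions exactly
  by construction; real scatter is only approximately affine.
* ENVI support covers flat binary BSQ/BIL/BIP with plain-text headers;
  exotic header dialects are not parsed.
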