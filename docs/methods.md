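# Methods

`kernelspec` reimplements a hyperspectral-imaging workflow for testing the
varietal purity of waxy maize (corn) seed: individual kernels are imaged as
VIS/NIR reflectance cubes, and a classifier assigns each kernel to one of
four varieties from its reflectance spectrum, its shape, and its surface
texture. Because no public seed-image dataset accompanies the original
study, every stage runs against a synthetic cube generator with full ground
truth; the generator is a first-class, tested module, and all headline
numbers in this repository are computed on its output.

## Imaging model and calibration

A hypercube is a (rows x cols x bands) array with a strictly increasing
wavelength axis; the default instrument profile is 477 bands spanning
400-1000 nm (1.26 nm spacing). Raw counts are converted to relative
reflectance with the standard dark/white correction

    I = (I0 - B) / (W - B),

where `B` is the dark-current frame and `W` the white-panel frame. Frames
may be full-frame, per-line (line-scan cameras), or per-band vectors; any
pixel-band with `W - B <= 0` is carried in an explicit validity mask and
excluded from downstream means rather than propagated as inf/nan. Cubes are
stored as plain ENVI (text header + flat binary, BIL or BSQ read, BSQ
written); round-trips are bit-exact for the supported dtypes.

## Segmentation and spectra

Kernels sit on a matte black stage, so one band separates them from
background. `pick_segmentation_band` returns the band maximizing the mean
reflectance contrast between a kernel ROI and a background ROI; on both real
and synthetic seed it lands near 850 nm, and the pipeline thresholds that
band (Otsu by default; a fixed threshold is accepted), labels 8-connected
components, drops components under 50 px, and orders regions row-major by
centroid. Touching kernels are not split — the acquisition protocol places
seeds separately — but area outliers (> 2.5x the median) trigger a warning.
Each region yields one mean spectrum over its valid pixels.

## Preprocessing

Spectra are cropped to 430-980 nm (the camera's SNR degrades at both ends)
and Savitzky-Golay filtered with window 21 and polynomial order 2; the first
derivative removes per-kernel baseline and scale effects. Derivatives are
expressed per nm by dividing by the mean band spacing (disable with
`scale_by_spacing=False`); edges use scipy's polynomial fit on the truncated
window. All spectral modeling downstream (band selection and the spectral
feature groups, including "full bands") uses this preprocessed matrix: the
derivative removes the per-kernel scale/tilt nuisance that would otherwise
dominate a raw-reflectance comparison between full and selected bands.

## Wavelength selection

**SPA (successive projections algorithm).** Starting from a column k(0),
each round projects every unselected column onto the subspace orthogonal to
the last selected column — candidates are mutated in place, so after n
rounds every candidate is orthogonal to all n selected columns — and picks
the candidate with the largest remaining norm. This greedy recursion is
verified in tests against a from-scratch QR re-orthogonalization oracle on
hundreds of random matrices. Selection order is independent of the model
size N, so one run at max(N) yields every prefix.

The model size is chosen by an outer loop: for each candidate start and each
N in a grid (default 5..30 in steps of 5 at study scale), the selected bands
feed a PLS-DA model scored by 5-fold cross-validated RMSE on one-hot class
targets (folds stratified, fixed seed; components = min(N, 10)). "Minimal
and steady" RMSE is operationalized as: among all (start, N) within 1%
relative of the global minimum RMSE, take the smallest N, then the smallest
start index. By default every band is a candidate start; at study scale the
pipeline restricts the search to the 8 largest-norm columns, which we have
not observed to change the chosen set but removes a ~50x constant from the
CV loop.

**PLS-DA coefficient ranking.** A PLS2 regression of one-hot class
indicators on the preprocessed spectra (scikit-learn's NIPALS
implementation, centered, unscaled; latent-variable count chosen by the
minimum venetian-blind 5-fold RMSECV, searched up to 15) yields a bands x
classes coefficient matrix; bands are ranked by their largest absolute
coefficient across classes. The kept count is a free parameter, defaulting
to 26 (germ-up) and 19 (germ-down) per side. NIPALS was preferred over
SIMPLS simply because it is what the established library provides; both are
deterministic, and for these well-conditioned problems they agree to within
the tolerances used anywhere in this package.

## Image features

**Shape (5 features, from the 850 nm segmentation mask).** Area is the mask
pixel count. The perimeter is the 8-connected Moore boundary chain length
with sqrt(2) weights on diagonal steps, which tracks smooth outlines better
than a pixel-edge count; circularity = 4*pi*area/perimeter^2 (exactly 1 for
a circle), aspect ratio = major/minor axis of the second-moment ellipse,
roundness = 4*area/(pi*major^2), solidity = area / pixelized-convex-hull
area. Note that discretization biases these slightly below their continuum
values: a rasterized 40x20 px ellipse measures solidity 0.972, not 1, and
the tests pin such computed values rather than idealized ones. Regions one
pixel wide are rejected.

**Texture (8 features).** Per band, a symmetric gray-level co-occurrence
matrix is built at displacement 1 for orientations 0/45/90/135 degrees,
counting only pixel pairs with both endpoints inside the kernel mask, after
rescaling the masked intensities of that band to 64 gray levels (the camera
is 12-bit; 64 levels keep kernel-sized matrices well populated). Energy
(sum P^2), contrast (sum (i-j)^2 P), correlation (0 when a marginal SD
vanishes), and entropy (base 2) are averaged over the four orientations,
then summarized by their mean and sample SD (ddof=1) across bands 51-477
(the first 50 bands are noise-dominated on this camera) — 8 numbers per
kernel. The SD-across-orientations alternative is available via
`sd_over='angles'`. Implementation note: moment statistics are computed
directly as sample means over the pixel pairs, and energy/entropy from one
sparse unordered-pair histogram per kernel; the fast path is tested for
exact agreement with the explicit per-matrix route.

## Classifiers and evaluation protocol

Feature tables carry group-tagged columns (spectral_full, spectral_spa,
spectral_plsda, morphology, texture); the six compared inputs are full
bands, image features (5+13), each selected set, and each selected set +
image features. The split is stratified and seeded: 100 train / 50 test per
variety; per-column z-scoring statistics are computed on training rows only.

The SVM is C-SVC with an RBF kernel (one-vs-one), grid-searched over
C, gamma in 2^-10..2^10 by 5-fold CV accuracy on the training set, ties
resolving to the smallest C then gamma. `GridSpec`'s default is the full x2
exponent step (21x21); the pipeline default uses step 2 (11x11), which we
found indistinguishable in chosen accuracy on this data at a quarter of the
cost. PLS-DA classifies by the argmax of the predicted one-hot scores with
11 latent variables (capped at capacity), and reports both its test-set
confusion (the headline number) and its leave-one-out training accuracy,
since either convention appears in the chemometric literature.

## The synthetic study

The generator emulates the study conditions: 4 varieties (HANG, SU, HU,
YAN) x 150 kernels x two sides (germ up / germ down), imaged in batches of
24 non-touching kernels on 52 px grid cells, 477 bands over 400-1000 nm,
raw counts built as B + (W-B)*R with a smooth lamp spectrum in W. Per-kernel
reflectance is

    R(x, y, l) = curve(variety, side, l) * texture(x, y) + noise(x, y, l),

with:

* **curves** — a shared logistic-like baseline (0.15 in the blue rising to a
  0.60 peak at exactly 850 nm, so kernel/background contrast always peaks
  there; background reflectance 0.04) plus 2-3 variety- and side-specific
  Gaussian bumps of |amplitude| 0.01-0.036. Germ-down curves are scaled by
  0.97.
* **kernel-level spectral variability** — each kernel perturbs its class
  curve by a random overall scale (sd 4%), a linear tilt (sd 0.035 across
  the range), and six smooth random Gaussian wiggles (amplitude sd 0.034,
  width 38 nm). This, not pixel noise, is what makes varieties overlap:
  region means average pixel noise away (sd 0.01 per pixel-band), as they
  would on a real camera.
* **shape** — rotated ellipses (variety-specific semi-axis means 14.8-18.6
  x 10.0-12.8 px, sd 0.9/0.7) with a smooth periodic radial roughness
  (harmonics 2-5, variety-specific amplitude 1.5-4%) controlling
  circularity and solidity.
* **texture** — a unit-mean multiplicative Gaussian random field per kernel
  (variety-specific amplitude 0.05-0.14 and correlation length 1.5-4 px,
  each jittered per kernel by a lognormal factor of sd 0.18-0.20),
  controlling GLCM contrast and entropy.

Two design elements are deliberate. First, the side disparity: SU and HU
have nearly identical germ-up curves (their germ-up bumps differ only by
~0.01 below 680 nm, and neither has structure in 680-940 nm) but clearly
distinct germ-down curves. Second — symmetrically — HANG and YAN are nearly
identical germ-down. Each side therefore carries exactly one spectrally
ambiguous variety pair, and both pairs are well separated in shape and
texture. This is what gives feature fusion a genuine, seed-stable gain over
spectra alone, rather than a gain that appears and disappears with the test
split: spectral-only accuracy sits at ~90-97%, image-only at ~85-91%, and
SPA+image fusion at ~96.5-99% across seeds, reproducing the qualitative
ordering fusion >= spectral-only >= image-only. These parameter values were
fixed once, while building the generator, to land in that moderate-SNR
regime, and are not adjusted by any test.

What the generator does **not** emulate: optical blur and chromatic
aberration, specular glints, partial-pixel kernel edges, touching kernels,
spatially varying illumination within a frame, wavelength-dependent texture,
and real biochemical absorption features. Passing tests therefore
demonstrate that the pipeline recovers structure of the kinds the generator
encodes at realistic sizes and noise levels — not that the specific
wavelengths or accuracies reported here transfer to real seed lots.

## Numerical and procedural choices

* All randomness flows from one seed per run, fanned out to fixed per-stage
  seeds (`stage_seed`), so stages are independently reproducible; a
  provenance JSON records config, versions, and seeds.
* SPA stops early with a warning when remaining projections fall below
  1e-10 of the largest column norm (rank exhaustion).
* GLCM matrices must sum to 1 within 1e-8 (`glcm_stats` rejects others);
  correlation is defined as 0 for degenerate marginals; quantization maps
  the masked min..max to 0..63, constant bands to level 0.
* Ties: the segmentation band argmax takes the lowest band; SPA's plateau
  rule takes smallest N then smallest start; the SVM grid takes smallest C
  then gamma; PLS-DA component choice takes the smaller count.
* Stage problem sizes at study scale — batches of 24 kernels, the 8-start
  SPA search, the 11x11 SVM grid — are the package defaults chosen to keep
  a full two-side study around three minutes on one core; all are config
  fields, and the exhaustive settings are one constructor argument away.

## Known limitations

* The per-kernel texture field is spectrally flat, so GLCM statistics vary
  across bands only through quantization and pixel noise; their band-SDs
  are consequently small and carry less class signal than the means.
* PLS-DA-coefficient band selection underperforms SPA here (as it did in
  the original study); no attempt is made to tune its kept-band count.
* The Moore-chain perimeter slightly underestimates boundary length for
  very small regions (< ~100 px), inflating circularity; kernels are an
  order of magnitude above that.
* `spa_choose_n` evaluates O(|starts| x |n_grid|) PLS-CV fits; with
  `starts=None` (every band) at 437 bands it is exact but ~50x slower than
  the default top-norm-8 search.
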