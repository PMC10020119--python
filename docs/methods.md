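# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `mesohist`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Diffusion tensor estimation (`mesohist.dti`)

The signal model is the Gaussian (monoexponential) tensor model
S = S₀ exp(−b gᵀDg). The fit is *ordinary* (unweighted) least squares on
log-signals over all measurements jointly, with ln S₀ a free parameter: the
design row is [1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz]
against the parameter vector (ln S₀, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz). No
separate b0 image is assumed; the lowest shell (b = 100 s/mm²) anchors the
amplitude. The default acquisition is three shells (b = 100, 1000,
3000 s/mm²) on a six-direction electrostatically optimized (icosahedral)
set, overridable from bval/bvec or CSV protocol files. Gradient timing
(δ, Δ, t_eff) is carried as metadata only — the Gaussian model does not use
it.

Numerical conventions:

* **Nonpositive signals.** Voxels with any S ≤ 0 (or non-finite) are masked
  invalid rather than floored, keeping the log-linear model well defined.
  The Rician noise floor guarantees positive magnitudes on real data, so
  this mainly guards synthetic or preprocessed inputs.
* **Negative eigenvalues.** After eigendecomposition, negatives are clamped
  to zero *for the anisotropy metrics* (FA, FA_IP are then guaranteed in
  [0, 1]) while MD is computed from the raw trace, which keeps the MD
  estimator unbiased under noise; clamped voxels are flagged and the raw
  eigenvalues retained.
* **Degenerate FA_IP.** Where λ₁ + λ₂ = 0 the ratio is defined as 0 (the
  isotropy limit), matching the SA convention.
* **Coordinate convention.** Arrays are (row = y, col = x), 0-based, with
  physical pixel centers at (i + 0.5)·resolution; the histology section
  plane is the MR (x, y) plane.
* **Smoothing.** The final σ = 40 μm Gaussian is applied to the *derived*
  parameter maps, not the raw signals, as mask-aware normalized convolution
  (invalid cells contribute zero weight; a constant map is unchanged;
  values cannot leave the input range). Reflect padding everywhere.

## Histology features (`mesohist.histology`)

RGB sections are collapsed to one channel either by Rec. 709 relative
luminance (default) or by projecting per-pixel optical density onto the
hematoxylin stain vector — the color-to-scalar step is a free choice, and
H&E contrast is primarily absorbance, so both are offered.

The structure tensor uses Gaussian-derivative gradients at σ = 0.25 μm
(0.5 px at the 0.5 μm/px scan resolution) and Gaussian integration of the
gradient products at σ = 15 μm (30 px). Downsampling to the 200 μm MR grid
(400×400 px blocks, integer block ratio enforced, trailing partial blocks
dropped) has two modes:

* **tensor-average** (default): block-mean of the components Hxx, Hxy, Hyy.
  Orientation is preserved, which the directionally encoded (DEC)
  renderings require.
* **eigenvalue-average**: block-mean of the *sorted* eigenvalues into an
  axis-free diagonal tensor. This follows the literal "average the
  eigenvalues within an MR voxel" reading; it discards orientation and
  scores mixed-orientation blocks as anisotropic (the mean of sorted
  eigenvalues never cancels). The two modes genuinely differ on such
  blocks — a test pins both against a brute-force per-pixel oracle.

SA = (λ₁ − λ₂)/(λ₁ + λ₂) with λ₁ ≥ λ₂ ≥ 0, defined 0 on featureless blocks,
then σ = 40 μm smoothing. SA is invariant to global intensity scaling
(H is quadratic in the image; the ratio cancels). For DEC the structure
orientation is the *minor* eigenvector of H: gradients run perpendicular to
stripes, so the minor axis points along the structures, matching the
diffusion tensor's major axis.

Cell density bins nucleus centroids into MR cells with half-open
[left, right) intervals per axis (points exactly on the far boundary are
excluded), so unnormalized counts sum exactly to the in-grid centroid
count; normalization divides by the sample maximum so the map peaks at 1.
Nucleus *detection* is out of scope — centroid tables are an input.

## Coregistration (`mesohist.registration`)

Landmark-based, two stages in fixed order: a closed-form 2D Procrustes
rigid fit (optional isotropic scale via a flag, since source protocols do
not always state whether "rigid" included scale), then a thin-plate spline
(kernel r² log r) fitted on the rigid-prealigned points. TPS regularization
defaults to 0 (exact interpolation, verified to 1e-8 μm); the bordered
system is solved directly and degenerate configurations (fewer than 3
pairs, collinear or duplicated moving points) raise typed errors. For
affine-consistent landmarks the kernel weights vanish (affine reduction), a
property asserted per fit in tests.

Resampling uses the pullback convention: the transform handed to
`apply_transform` must map target (MR) coordinates into source (histology)
coordinates. Rigid transforms invert analytically; the TPS pullback is
fitted on the swapped landmark pairs, exact at the landmarks for zero
regularization. Interpolation is bilinear for scalar maps (a convex
combination, so resampled values never leave the source range) and nearest
for masks; cells mapping outside the source, or onto invalid cells, come
back invalid. Histology is always warped onto the MR grid, the analysis
grid, not vice versa.

## Association statistics (`mesohist.association`)

The within-tumor ROI is the intersection of the MR and histology tissue
masks eroded by a disk structuring element (radius 1 MR cell by default;
radius 0 gives the pure intersection).

Model families: polynomials of degree 1–3 by OLS; a quadratic constrained
to be monotone decreasing over the *training data range* (for a quadratic,
derivative ≤ 0 on an interval ⇔ at both endpoints, so the convex QP has two
linear constraints and is solved exactly by enumerating the four active
sets); and a no-intercept line. Data-range rather than global enforcement
of the monotone constraint is a deliberate choice: a globally monotone
quadratic would be degenerate (linear), and the constraint's purpose is to
encode the expected negative CD–MD association where data exist.

R²_OS = 1 − MSE_model/MSE_μ with both MSEs on held-out voxels and MSE_μ
scoring the mean of the *measured test values*. This makes numerator and
denominator share degrees of freedom, so models of very different
complexity are comparable; a side effect is that the trivial
train-mean predictor scores slightly below zero on average, which the
noise-only calibration test quantifies. Splits take ⌊0.8·n⌋ training cells
uniformly at random; 1000 repeats; all driven by one `numpy` Generator
seed, reproducible bit-for-bit. Summary statistics use the population SD
(divide by n); CoV = SD/mean. Pearson correlations use the two-sided
t-approximation for p-values, with no multiple-testing correction. The
benchmark slot of RR²_OS is a plain pair of MSEs, so any external predictor
(e.g. a learned model's output) can be compared; the test suite exercises
the sign conventions with deliberately crippled and oracle benchmarks.

Whole-sample (inter-tumor) association takes each sample's ROI means and
reports Pearson r and R² = r²; ROI means (not full-mask means) are used.

## Synthetic phantoms (`mesohist.phantom`)

The generator produces the statistical structure the analysis assumes, not
photorealistic tissue:

* **ICVF field**: Gaussian-filtered white noise rescaled to span the
  configured range (default 0.10–0.70, correlation length 4 cells on the
  default 40×40 grid at 200 μm).
* **MD link**: MD = d_free·(1 − ICVF), exact on feature-free cells, with
  d_free = 1.0×10⁻³ mm²/s as an ex-vivo-plausible free diffusivity. This
  encodes the volume-fraction picture of MD (near-zero intracellular
  diffusivity, extracellular fraction 1 − ICVF).
* **Cell counts**: round(density_max·ICVF), density_max = 150 per
  200 μm cell, so CD tracks ICVF up to rounding. The *large-cell mode*
  holds ICVF (hence MD) constant while counts follow an independent smooth
  field — the regime where cell density varies but MD does not, which the
  decoupling tests reproduce.
* **Orientation and dispersion**: a smooth axial orientation field θ and a
  wrapped-normal dispersion SD σ_θ (default range 0.1–0.6 rad); voxel-scale
  in-plane anisotropy is attenuated by the circular-variance factor,
  FA_IP = a_max·exp(−2σ_θ²) with a_max = 0.6. Tensors are assembled with
  λ₃ = λ₂ (through-plane equal to the in-plane minor by default) and the
  in-plane sum chosen so the trace reproduces MD exactly.
* **Mesoscopic features** (off by default, densities configurable):
  vessel-like corridors (near-free water), microcyst clusters (low MD),
  psammoma-like inclusions (signal voids via S₀ ≈ 0). Feature cells
  override the tissue model and are labelled in the truth.
* **Noise**: Rician, S_noisy = √((S + n₁)² + n₂²) with σ = S₀/SNR defined
  at b = 0 (default SNR 50); SNR = ∞ returns exact noiseless signals.

The histology renderer draws an eosin-toned cosine fiber texture along a
seam-free bilinear upsampling of θ (phase jitter ∝ dispersion) and
hematoxylin-toned nuclear ellipses at dart-thrown centroid positions with a
5 μm minimum spacing (shortfalls are reported). Nuclei elongate along the
local fiber axis with angular jitter growing with dispersion, as in fibrous
tissue; this also means the nuclear and textural gradients carry the same
orientation signal. The rendering is deliberately stylized: it feeds the
structure-tensor and centroid-count code paths, which is all the pipeline
consumes. Passing tests on phantoms therefore demonstrate correctness of
the *pipeline* under the stated generative assumptions — they do not
certify stain variability, scanner artifacts, sectioning deformation
beyond what the landmark registration models, or biological realism of the
texture.

## Problem sizes

The default test and acceptance runs use 40×40-cell phantoms (1600 voxels,
matching a ~8×8 mm section at 200 μm) for the signal-only analyses and
8–10 cells per side (3200–4000 px square images at 0.5 μm/px) where the
full histology rendering and structure-tensor arm is exercised; the
repeated-split analyses use the standard 1000 repeats. These sizes give
stable medians while keeping a full run to minutes on one CPU.

## Known limitations

* The through-plane direction is untreated: sections are single 2D planes,
  and FA (as opposed to FA_IP) is compared only incidentally.
* The monotone-quadratic and origin-line constraints encode expected
  biology, not a biophysical model; none of the model families has one.
* The benchmark-predictor interface replaces any learned image-to-parameter
  model; no network is trained or shipped.
* Rician-bias-corrected tensor estimators, eddy-current/motion correction,
  and non-Gaussian encodings are out of scope.
* `eigenvalue-average` downsampling discards orientation by construction;
  DEC rendering refuses it.
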