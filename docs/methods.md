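# Methods

This note documents the models the package implements, the conventions and
numerical choices behind them, what the synthetic phantom generator does and
does not emulate, and the known limitations. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Two-material decomposition

The forward model is linearized (monochromatic) Beer–Lambert attenuation: at
each pixel the low- and high-energy attenuation values are

    A_L = μf_L·t_fat + μl_L·t_lean
    A_H = μf_H·t_fat + μl_H·t_lean

with tissue thicknesses in cm of beam path. Decomposition inverts this 2×2
system per pixel; negative solutions (attenuation pairs outside the physical
cone spanned by the two basis materials, e.g. from noise) are clamped to zero
and counted. Derived maps: total thickness `t_fat + t_lean`, leanness
`t_lean/(t_fat + t_lean)` ∈ [0, 1], and the R-value `A_L/A_H`.

The effective per-cm attenuation coefficients of fat and lean tissue at the
two beam energies are scanner-calibration quantities; the shipped defaults
(fat 0.218/0.182, lean 0.262/0.192 cm⁻¹ at low/high energy; densities
0.92/1.05 g·cm⁻³) are physically plausible for adipose and lean soft tissue
at ~40/~70 keV effective energies and are configurable via
`CalibrationTable`. Everything that forward-simulates uses the same table it
later decomposes with. Under the linearized model the R-value of a
fixed-composition body is independent of thickness (the ratio of two linear
forms); the real-scanner thickness dependence of R caused by beam hardening
is polychromatic physics and is deliberately outside this model. Bone is not
a third compartment: synthetic bone (the spine column) contributes to the
lean channel, matching the convention that fat-free tissue means lean plus
bone.

## Raster pathway

The native scanner grid is 150 rows × 327 columns with anisotropic
2 mm × 13 mm pixels; images are resampled along y by a factor of 6.5 to a
square-pixel 975 × 327 grid. The y-resampler uses endpoint-aligned linear
interpolation (output row j reads input coordinate `j·(rows−1)/(rows_out−1)`),
chosen so constants are preserved exactly and a linear ramp survives an
upscale/downscale round trip to machine precision; nearest-neighbor is
available behind a flag. All quantization (8-bit export, 16-bit TIFF
storage) rounds half away from zero; 8-bit output exists only for display
and annotation-software compatibility — all modeling runs in physical units
(cm, fractions), so quantization noise never enters a covariance. Masked
histogram equalization (inclusive empirical CDF over body pixels, output in
(0, 1]) is display-only. Coordinates are 0-based with x = column,
y = row, origin top-left.

## Landmark schemes and meshes

The 82-point full-body scheme covers the skin outline plus internal bony and
soft-tissue landmarks (clavicles, lung apices/bases, rib margins, pelvic
brim, femoral heads, spine-adjacent midline points); the 52-point
extended-torso subset keeps the torso, upper arms and upper legs and drops
the head and the forelimbs. Published sources for such schemes are
pictorial, so the shipped scheme is generated from the parametric template
body in code: names, left/right symmetry pairs, midline indices, the torso
subset, and a Delaunay triangulation of the template landmarks restricted to
the body silhouette (triangles whose centroid falls outside the slightly
buffered outline are dropped so the mesh cannot bridge the concave gaps
between limbs and torso; winding is normalized to positive signed area).
Reflection relabels left/right pairs while mirroring x about the image
axis; it is an exact involution and commutes with the torso subset because
the subset is symmetry-closed.

The semi-automatic landmark search is a deliberately simplified constrained
local search: per-point normalized-cross-correlation template matching
within a ±6 px window alternates with a hard projection onto the shape-model
subspace, mode scores clipped to ±3√λ, until the mean displacement falls
below 0.25 px or 20 iterations. It does not train per-landmark response
models or use multi-resolution pyramids; on a featureless image the NCC step
is a no-op and the search settles at the shape-space projection of its
initialization.

## Shape, texture and appearance models

Alignment is translation-only (common center of gravity) by default; a full
Procrustes variant (rotation and scale removal) exists behind a flag because
the stronger normalization is sometimes wanted, but translation-only is the
default behavior. PCA is an exact eigendecomposition of the sample
covariance, taken in the smaller of the sample/feature dimensions (Gram
trick), with no randomized solvers; each eigenvector's sign is fixed by
making its largest-magnitude component positive, so fitted models are
bit-reproducible across runs. Mode retention keeps the smallest k whose
cumulative explained-variance fraction reaches the threshold (default 0.95).

Texture vectors are sampled over the in-mask pixels only, in row-major scan
order with channels interleaved per pixel (single-channel R-value or
thickness layouts, or the two-channel thickness+leanness layout that the
red/green hybrid display encodes). The reference frame places the mean shape
in a raster with a 5% bounding-box margin; an `output_scale` factor (0.5 in
the demo) shrinks the frame raster, and hence the texture dimension, without
changing the geometry. Pixels on shared triangle edges belong to the
lowest-indexed containing triangle — a deterministic tie-break — and
sampling is bilinear with edge clamping so texture is continuous across
triangle boundaries.

The appearance model is a PCA over concatenated `[w_s·b_shape ; b_texture]`
score vectors. The shape weight defaults to `w_s = sqrt(Σλ_g / Σλ_s)`, which
equalizes the total variance of the two blocks — the standard commensuration
when one block is in pixels and the other in physical intensity units; it is
a configurable scalar. Synthesis splits a combined vector into blocks,
renders the texture in the frame and warps it onto the synthesized shape
(raising an error naming the first folded triangle if the shape turns a
triangle inside out). Encoding is pure orthogonal projection given
annotations; iterative appearance-driven landmark search is out of scope.
The encode∘synthesize round trip is exact (machine precision) in the model's
own domain — landmarks plus frame-domain texture — which `SynthesisResult`
exposes alongside the rendered image; re-encoding the rendered image instead
costs one extra bilinear warp of error.

## Statistics

Bivariate associations: Pearson r with its t-test p for continuous
covariates, univariate logistic Wald p for binary ones. Logistic models are
fitted by Newton scoring (IRLS) to a coefficient tolerance of 1e-8; perfect
separation is detected by coefficient blow-up and handled by capping |β| at
25 and flagging the model rather than diverging. Stepwise selection is
forward entry by the smallest likelihood-ratio p ≤ p_enter (ties to the
lower mode index) followed by backward elimination of any term whose
exclusion p > p_stay, both defaulting to 0.05, over the candidate pool of
retained modes; likelihood-ratio rather than Wald tests were chosen because
they are better calibrated in small samples and invariant to
parameterization. AUC is the rank-based Mann–Whitney statistic with ties
counted 1/2. Models are fitted on one half of a cohort and evaluated on the
disjoint other half via a stratified alternating split, so both halves
always contain both classes. A fitted logistic direction is visualized by
normalizing `d = Σβᵢeᵢ` to unit Mahalanobis length (√(Σdᵢ²/λᵢ) = 1) and
synthesizing at ∓k standard deviations; the difference image colors
high-risk excess red and low-risk excess green. The Mahalanobis
normalization is this package's choice of the ±k-SD scale for a
multi-mode direction; it degenerates to the single mode's ±k√λ when only
one coefficient is present.

## Synthetic phantom generator

A phantom is a union of analytically simple parts — circular head, capsule
neck/limbs, a torso with piecewise-linear half-width
(shoulder → waist → hip) — each with an elliptic cross-section along the
beam, so thickness falls off as `sqrt(1−(d/w)²)` from the part axis and
every landmark and per-pixel thickness has a closed form. The torso's top
and bottom end in an elliptic thickness roll-off (length 30 px): bodies have
sloping shoulders and hips, and a flat-cut discontinuity would dominate
registration residuals with artifactual variance. Forward simulation
integrates the analytic fields over each pixel footprint (3×3 midpoint rule)
rather than point-sampling, modeling the area-integrating detector; because
the attenuation model is linear this commutes with the averaging, and the
decomposition round trip against the same integrated fields is exact.
Measurement noise is additive Gaussian on attenuation (not Poisson) — simple
and sufficient to exercise PCA noise floors.

Cohorts draw three generative factors per subject — overall scale
(SD 0.04), torso width factor (SD 0.05) and trunk fat fraction (SD 0.06
around 0.32, with limb fat fractions tied proportionally) — plus per-limb
pose jitter (1.5°/1.0°/1.0°/0.8° SD for arm/forearm/leg/shank angles).
Binary group effects are specified in SD units of a factor and applied
±δ/2 symmetrically; group assignment is a balanced permutation, mirroring a
case-control design. Subjects whose geometry would leave the scan field are
rejection-resampled (capped at 20 draws). The demo's "sex-like" effect
(width +2.5 SD, fat −2.0 SD between groups) was chosen from normal theory:
the combined Mahalanobis separation d ≈ 3.2 gives an oracle AUC of
Φ(d/√2) ≈ 0.99, the regime of a strong anthropometric discriminator. All
randomness flows from a single seed through named SHA-256 substreams; a
fixed seed reproduces images and landmarks bit for bit.

Two generation grids exist. The default `native` grid follows the realistic
scanner pathway (anisotropic 150 × 327 sampling, then 6.5× y-upscaling); its
coarse 13 mm rows alias the steep thickness edges, which is faithful to the
instrument but adds texture variance that is not a function of the
generative factors. The `square` grid samples the fields directly at
975 × 327 and is the appropriate noise-free condition for exact-rank
experiments: on a pose-frozen, noise-free, square-grid cohort the
three-factor family yields exactly three appearance modes at the 0.95
threshold, while on the native grid the aliasing adds real extra modes.

What passing tests show, and what they do not: the phantoms have exactly
elliptic profiles, perfect landmark placement, no scatter, no beam
hardening, no bone compartment beyond a stylized spine, and group effects
that are linear in the generative factors. Results on them validate the
*machinery* — decomposition algebra, warp geometry, PCA correctness,
selection behavior, determinism — not the anatomical realism of any model
fitted to real scans.

## Problem sizes and runtime choices

The shipped demo uses n = 60 subjects (120 training samples after
reflection) with the frame at half resolution, which keeps the full pipeline
under half a minute on one CPU; the discrimination experiment in the
acceptance script uses the 200-subject case-control size split into
calibration and validation halves. Known-rank and sharpness experiments run
at n = 60; stepwise behavior is characterized on 100 seeded replicates of
n = 400 score matrices. These sizes are the package's own defaults, chosen
so that the full verification suite runs in minutes while the statistical
assertions retain comfortable margins.

## Known limitations

* The attenuation model is monochromatic and two-material; R-value thickness
  dependence (beam hardening) and a bone mineral compartment are not
  modeled, and scanner raw-file formats are not parsed.
* The landmark search is a simplified constrained local search, not a
  trained constrained local model; it assumes a reasonable initialization.
* Piecewise-affine warping is only C0 across triangle edges; curvature
  between landmarks is approximated by the mesh, which leaves small
  systematic texture residuals at part rims on deformed subjects.
* Stepwise p-value selection inherits the usual caveats of data-driven model
  selection (optimistic in-sample fit); the held-out AUC is the honest
  number.
* The mean-shape reference frame raster and its scale are configuration
  choices, not estimated quantities.
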