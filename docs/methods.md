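# Methods

## Angular conventions

All orientations are axial: a fibril axis has no polarity, so angles live
on a 180° circle. We use degrees, counter-clockwise positive, x axis = 0°,
folded into the half-open interval (−90°, 90°] with −90° identified with
+90°. Image arrays are stored row-major with row 0 at the top; the y axis
points up, so the row derivative is negated inside the estimator. Summary
angles of a sample (the "modal angle") are computed as the circular mean of
the doubled angle, which is exact across the ±90° wrap-around and is the
maximum-likelihood location for unimodal axial data.

## Orientation index

OI(θᵢ) = Σ N(θ)·cos 2(θ−θᵢ) / Σ N(θ), evaluated at bin centers. This is the
unique standard form with OI = 1 at θᵢ, −1 at θᵢ ± 90°, and 0 under
isotropy; it equals 2⟨cos²(θ−θᵢ)⟩ − 1. Discrete summation over exported
bins (not integration) is used because the input is a binned frequency
export; evaluating at bin centers makes the discretization error symmetric,
bounded by 2·sin(w·π/180) for bin width w (0.035 at the default w = 1°).
Histogram bin centers sit at integer multiples of the bin width
(…, −1°, 0°, 1°, …, 90°), so mass lying exactly on the x or y axis falls
in a bin centered there and the endpoint identities hold exactly. Polar
frequency histograms store N(θ)/ΣN(θ) losslessly; the radial-axis cap of
0.03 used for cross-panel comparability is applied only when drawing.

## Structure-tensor orientation estimation

Gradients are Gaussian-derivative filtered at σ_g (default 1 px, near the
smallest scale that suppresses pixel noise without blurring 2-px ridges);
the tensor J = ⟨∇I ∇Iᵀ⟩ is averaged with a Gaussian window σ_w (default
2 px, ~the fibril width, so each pixel sees one ridge). The reported angle
is the eigenvector of the smallest eigenvalue (the along-ridge direction,
perpendicular to the dominant gradient). Coherence is the eigenvalue
contrast (λ₁−λ₂)/(λ₁+λ₂); energy is the trace.

Numerical choices:

* Tensors with energy ≤ 1e−12 × max energy are treated as degenerate:
  angle pinned to 0°, coherence 0. This keeps angle and coherence maps
  exactly invariant under intensity rescaling (flat regions would otherwise
  report rounding noise).
* The foreground mask keeps pixels with energy above its 50th percentile
  (configurable); with no mask, flat background would flatten N(θ) toward
  isotropy. A margin of ceil(3 σ_w) at the image border is always excluded
  because the averaging window is truncated there and padding dominates the
  tensor.
* A constant image yields an all-false mask, not an error; building a
  histogram from an empty mask is an error (no measurable structure).

Known estimator limitation: at fibril end-caps the local structure is a
blob, not a ridge, and the tensor reports an orientation up to 90° off with
high coherence. On noise-free single-orientation phantoms with realistic
slender fibrils this leaves ≥ 95% of foreground pixels within 2° of truth
and biases pipeline OI by ≲ 0.01–0.015 toward larger values at low order
(measured against the analytic von Mises Bessel-ratio); crossing fibrils
add a comparable opposite-signed pull. These are properties of the method
class, not artifacts of the implementation.

## Synthetic fibril phantoms

Fibrils are straight segments with a Gaussian cross-section (FWHM = the
sampled thickness), composited with per-pixel maximum, then blurred
(σ = 0.7 px, a modest point-spread width), offset by a background level
(0.05) and corrupted with additive Gaussian noise (σ = 0.01) before
clipping to [0, 1]. Defaults are a 512×512 field with 300 fibrils of
length 40–120 px and thickness 2–4 px — dense enough to resemble a
labelled-collagen micrograph while keeping fibrils individually resolvable.
Tests that quantify per-pixel estimator accuracy use a slender variant (100
fibrils, 150–300 × 1.5–2.5 px, no noise) so that the ambiguous end-cap area
stays a small fraction of ridge area, as it is for fibrils spanning a real
field of view. The ground-truth map records each fibril pixel's segment
angle (later fibrils overwrite at overlaps), with NaN on background.

The angular law is uniform, delta, or axial von Mises (density ∝
exp(κ·cos 2(θ−μ))), the latter chosen because its OI has the closed form
I₁(κ)/I₀(κ), giving an analytic end-to-end calibration target; it is
sampled exactly by drawing 2θ from a circular von Mises. The phantoms do
not simulate confocal optics (anisotropic PSF, depth attenuation),
photobleaching, fibril curvature or branching, so passing calibration here
demonstrates correctness of the estimation chain, not robustness to every
real-microscope artifact.

3-D ensembles are unit vectors with antipodal symmetry: isotropic (normal
deviates, normalized) or planar with azimuths from an angular law and a
Gaussian out-of-plane jitter (σ = 5°) so plane projections are well
defined.

## Affine reorientation model

Assumptions: the elastomer is incompressible, deformations are homogeneous
and diagonal in the chamber frame, and a fibril is a passive line element
of the matrix (affine kinematics; no fibril–fibril mechanics, no
viscoelastic lag). Pre-deformation by λ along the strain axis gives
diag(λ^−1/2, λ, λ^−1/2); release gives diag(λ^1/2, λ^−1, λ^1/2) — each with
determinant 1 (volume conservation, enforced to 1e−9). Fibril axes
nucleate isotropically in the deformed chamber (fibrillogenesis starts
after loading), are mapped v → F·v/‖F·v‖, and OI is computed on xy-plane
azimuths with unit weight per fibril; projection-length weighting is not
applied because pixel-count analyses of in-plane micrographs provide no
such rule. The closed-form consequences — tan θ_rs = λ^−3/2 tan θ₀ (xy),
tan φ_rs,yz = λ^3/2 tan φ₀,yz, φ_xz invariant — serve as the oracle the
vector implementation is tested against at 1e−9.

The pure affine prediction is strictly monotone in ΔL/L; the experimental
plateau in measured alignment above ΔL/L ≈ 0.3 is deliberately not
reproduced — saturation involves fibril interactions outside this model.
This is documented behaviour, not a defect.

## Gelation timing (strain-duration window)

Fibrillar fraction over time follows a logistic f(t) = 1/(1 + exp(−r(t −
t_half))), the standard sigmoid for nucleation-growth kinetics with lag,
growth and plateau phases. Kinetics are constrained at construction to
f(t_lag) ≤ 0.05 so the lag phase is a genuine lag while keeping
f(t_half) = 0.5 exactly. Defaults: t_lag = 3 min, t_half = 7 min,
r = 0.75 min⁻¹ — calibrated so fibrils are essentially undetectable at
3 min (f ≈ 0.047) but present at 5 min (f ≈ 0.18), the reported detection
window; r is the smallest round value compatible with the lag constraint at
this (t_lag, t_half).

The mixture model pools three populations at their xy azimuths:

1. fraction f(t_D) assembled before release — affinely reoriented if
   f(t_D) ≤ f_jam, else left isotropic (a hard jamming threshold, default
   f_jam = 0.6, abstracting "too dense to reorient");
2. of the remaining 1 − f(t_D), a fraction `template_efficiency` adopts
   the reoriented distribution (growth templated on aligned fibrils),
   active only when a reoriented population exists;
3. the rest assembles isotropically in the restored chamber.

`template_efficiency` defaults to 0.5: templating is real but imperfect
(new fibrils also nucleate de novo); at 1.0 the model collapses to the pure
affine limit whenever any reoriented material exists, erasing the
dependence on t_D below jamming. The model yields the observed window:
little alignment for t_D ≪ lag (nothing to reorient or template),
maximal alignment at intermediate t_D, and none after jamming.

## Spine classification

Thresholds are applied inclusively (the natural reading of
"minimum"/"maximal"): retained as a spine iff volume ≥ 0.020 µm³ and
max width ≤ 3 µm and 0.2 µm ≤ length ≤ 2 µm; mushroom iff head ≥ 0.35 µm
and head:neck ≥ 1 (an unmeasurable neck, diameter 0, fails the criterion);
otherwise stubby iff volume ≥ 0.040 µm³; otherwise thin. Long slender
protrusions (> 2 µm) are filopodia-like and are reported as rejected
rather than as a positive class. The volume thresholds are quoted both as
voxel counts (5, 10) and in µm³ (0.020, 0.040); at the spine voxel size
0.11 × 0.11 × 0.42 µm these disagree (5 voxels = 0.0254 µm³). The µm³
values are authoritative here and `voxels_to_volume` keeps the discrepancy
visible rather than silently resolving it.

The protrusion generator draws descriptors from stage-dependent uniform
ranges: immature cultures (DIV10) are dominated by filopodial geometry,
mature ones (DIV21) by mushroom/stubby/thin spines. It exists to exercise
the decision rules and density computation; it does not model optical
measurement error on the descriptors.

## Problem sizes and determinism

Monte-Carlo checks use n = 10⁵ directions (standard error on OI ≈ 0.002)
and phantom suites of 4–6 images of 512² px; both complete in seconds on a
single core. All randomness flows through `numpy.random.Generator` seeded
explicitly; pipeline runs expand one global seed into per-stage substreams
via `SeedSequence` so any stage can be reproduced in isolation, and every
output directory carries a JSON manifest (parameters, seed, version) from
which the run is bit-for-bit reproducible.
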