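# anisoquant

Quantification of fibre alignment in fluorescence micrographs of fibrous
scaffolds (e.g. fluorophore-labelled collagen), and a 3-D affine model of
how strain release of a pre-deformed elastomeric culture chamber reorients
fibrils during collagen self-assembly. Written for tissue engineers and
image analysts who need a reproducible, scriptable version of the
OrientationJ-style "micrograph → orientation map → angular histogram →
orientation index" workflow, plus the mechanics that explain the measured
alignment.

## What it computes

**Orientation index (OI).** For an angular frequency distribution
N(θ) over θ ∈ (−90°, 90°] (θ measured from the x axis, fibrils axial so
θ ≡ θ + 180°) and a reference angle θᵢ,

```
OI = Σ_θ N(θ) · cos 2(θ − θᵢ) / Σ_θ N(θ)  =  2⟨cos²(θ − θᵢ)⟩ − 1
```

OI = 1 means perfect alignment at θᵢ, 0 an isotropic distribution, −1
perfect alignment perpendicular to θᵢ — a nematic-type order parameter.

**Per-pixel orientation.** N(θ) comes from a gradient structure tensor:
Gaussian-derivative gradients at scale σ_g, tensor-averaged with a Gaussian
window at scale σ_w; the eigenvector of the smallest eigenvalue gives the
local (along-ridge) orientation, with coherence (λ₁−λ₂)/(λ₁+λ₂) and energy
λ₁+λ₂ as confidence measures.

**Affine reorientation under strain release.** An incompressible elastomer
pre-deformed by λ = 1 + ΔL/L along y (transverse λ^−1/2) carries the
embedded viscoelastic matrix back by λ^−1 axially and λ^1/2 transversally
when released. A fibril axis v maps affinely to F·v, giving in closed form
tan θ_rs = λ^−3/2 tan θ₀ in the xy plane, tan φ_rs,yz = λ^3/2 tan φ₀,yz,
and an invariant xz angle. Pre-stretch (λ > 1) therefore aligns fibrils
along x, pre-compression along y. A logistic gelation curve with jamming
and templating terms models why alignment requires releasing the strain
within a window of the strain duration t_D.

**Dendritic protrusion classification.** The rule-based spine screen
(volume ≥ 0.020 µm³, width ≤ 3 µm, 0.2–2 µm length) and
mushroom / stubby / thin classification with inclusive thresholds, plus
protrusion density per 10 µm of dendrite.

Everything runs on synthetic data generated in-package: fibril phantoms
with pixel-level ground truth and controllable angular distributions, 3-D
fibril ensembles, and stage-dependent protrusion tables.

## Worked example

```python
from anisoquant import (AngularDistribution, ImageSpec, render_fibril_image,
                        structure_tensor_orientation, orientation_histogram,
                        orientation_index, modal_angle, predicted_oi_vs_strain)

spec = ImageSpec(n_fibrils=400, seed=42,
                 angular_distribution=AngularDistribution("axial_von_mises",
                                                          mean_angle=0.0,
                                                          concentration=2.0))
image, truth, fg = render_fibril_image(spec)
field = structure_tensor_orientation(image, sigma_gradient=1.0, sigma_window=2.0)
hist = orientation_histogram(field, bin_width=1.0)
res = orientation_index(hist, theta_i=0.0)
print(f"OI = {res.oi:.3f} (analytic I1(2)/I0(2) = 0.698)")
print(f"modal angle = {modal_angle(hist):.2f} deg")

curve = predicted_oi_vs_strain([0.0, 0.1, 0.2, 0.3, 0.4, 0.5], n=100_000, seed=1)
print(curve.to_string(index=False))
```

Output:

```
OI = 0.750 (analytic I1(2)/I0(2) = 0.698)
modal angle = -0.24 deg
 delta_ratio       oi      n
         0.0 0.001180 100000
         0.1 0.068498 100000
         0.2 0.133259 100000
         0.3 0.191268 100000
         0.4 0.246713 100000
         0.5 0.291259 100000
```

The phantom was drawn from an axial von Mises law with κ = 2, whose exact
OI is I₁(2)/I₀(2) ≈ 0.698; the single-image pipeline estimate lands near it
(per-image scatter is a few hundredths — average several images for tighter
estimates). The strain curve shows OI ≈ 0 with no strain and monotonically
better alignment along x as the pre-stretch ratio ΔL/L grows; negative
ratios (pre-compression) yield negative OI, i.e. alignment along y.

The same stages are exposed on the command line:

```sh
anisoquant synth --spec spec.json --out out/
anisoquant orient --image out/image.tif --out out/field.tif
anisoquant oi --hist out/field.csv --theta-i 0
anisoquant simulate --n 100000 --seed 1 --out curve.csv
anisoquant spines --in protrusions.csv --out classified.csv
anisoquant run --config run.yaml
```

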