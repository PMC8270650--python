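# diffusekit

Construction, quality scoring, and modelling of 3D anisotropic diffuse
x-ray scattering maps from rotation-series protein diffraction frames.

Bragg peaks encode only the average unit-cell electron density; the
continuous diffuse scattering between them is sensitive to spatially
correlated deviations from that average — i.e. to how atoms move
together.  The diffuse signal is weak, sits on a much stronger isotropic
background, and is easily contaminated by merging artifacts, so careful
image processing and honest quality metrics matter as much as the
physics.  `diffusekit` is for crystallographers and methods developers
who want to extract diffuse maps from their own rotation data, measure
how trustworthy those maps are, and fit simple motion models to them —
plus a fully synthetic data generator so every stage can be exercised
without beamline data.

## What it computes

**Maps.** Frames are cleaned (static mask; 11×11 window, 5σ outlier
rejection; exposure-scaled subtraction of paired non-crystal background
frames; polarization, solid-angle, detector-absorption and parallax
corrections; Bragg-pixel removal for |h − round h|, … ≤ 0.25), scaled to
a reference frame via radial intensity profiles, cleaned of residual
per-frame radial variation by PCA (top 3 components of the profile
matrix), and merged into a voxel grid sampled at integer Miller indices.
The merged volume is Friedel/Laue-symmetrized (2/m) and the radial
average subtracted, leaving the anisotropic diffuse map.

**Quality metrics.** Pearson correlations, overall and per resolution
shell:

- CC_Friedel / CC_Laue — map vs its own symmetrized version.  Inflated
  for noise: an i.i.d. random map gives 1/√(orbit size) ≈ 0.71 / 0.50.
- CC_1/2 — correlation between half-set means of symmetry-redundant
  observations; the sharper internal-consistency metric.
- CC_Rep / CC_Cross — mean correlation against replicate crystals /
  a different crystal form; the model-free reproducibility metrics.

**Models.** The liquid-like motions (LLM) model, with displacement
correlations decaying as exp(−r/γ):

    I_d(q) ∝ σ² q² e^(−σ²q²) [ I₀(q) ∗ Γ_γ(q) ],   Γ_γ(q) = 8πγ³ / (1 + γ²q²)²

(q in rad/Å here), with variants that keep the refined individual ADPs
(isotropic B_eq or full anisotropic U) and drop the overall
Debye–Waller factor, and an independent rigid-body translation (RBT)
model I₀(q)(1 − e^(−σ²q²)).  Fits maximize the model–data correlation
(CC_LLM, CC_RBT) by Powell search; ADP utilities include B_eq,
anisotropy ratios, and B_eq-preserving traceless anisotropic rescaling.

## Worked example

Simulate a replicate-quality dataset (256² detector, 120 × 1.5° frames,
monoclinic P2₁ toy crystal with LLM ground truth σ* = 0.4 Å, γ* = 7 Å),
run the standard pipeline, and fit the LLM:

```python
import diffusekit as dk
from diffusekit.models import fit_model, reference_intensity

spec = dk.SyntheticSpec(seed=1, hmax=16, n_frames=120, rotation_step=1.5)
model = dk.make_toy_model(spec)
truth = dk.make_truth_volume(model, spec.sigma, spec.gamma, "llm", "zero",
                             spec.hmax, oversample=2)
geometry = dk.default_geometry(256)
orientation = dk.make_orientation(spec)
crystal, background = dk.render_frames(truth, spec, geometry, orientation)

cfg = dk.PipelineConfig(hmax=16, resolution_limit=2.6,
                        n_profile_bins=120, n_shells=10)
result = dk.run_pipeline(crystal, background, geometry, orientation,
                         model.cell, cfg)

rep = result["reports"]
print(f"completeness  {100 * rep['completeness']['overall']:.1f} %")
for key, label in (("cc_friedel", "CC_Friedel"), ("cc_laue", "CC_Laue"),
                   ("cc_half", "CC_1/2")):
    print(f"{label:<11s}  {rep[key].overall:.3f}")

ref = reference_intensity(model.select_conformer("A"), spec.hmax, "zero")
fit = fit_model(result["laue_aniso"], ref, "llm", "zero", d_min=2.6,
                voxel_average=True)
print(f"LLM fit      sigma = {fit.sigma:.2f} A, gamma = {fit.gamma:.1f} A, "
      f"CC_LLM = {fit.cc:.3f}")
```

Output:

```
completeness  100.0 %
CC_Friedel   0.977
CC_Laue      0.966
CC_1/2       0.956
LLM fit      sigma = 0.36 A, gamma = 6.8 A, CC_LLM = 0.958
```

The 180° rotation covers every symmetry-unique voxel (100%
completeness).  The symmetry metrics sit near 0.97 — remember a pure
noise map would already score 0.71/0.50 — while CC_1/2 = 0.956 shows
genuine internal consistency.  The fit recovers the generating motion
parameters (σ within ~10%, γ within ~3% here) with a model–data
correlation of 0.96; `voxel_average=True` makes the forward model
average the correlation kernel over each voxel's merge acceptance box,
which removes the γ bias that point-sampling would introduce.

A command-line interface mirrors the library
(`diffusekit simulate | run | fit | ablate`); maps are written as plain
HKL tables and CCP4 volumes, reports as JSON.

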