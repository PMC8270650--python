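# Methods

`diffusekit` turns rotation-series x-ray diffraction frames into 3D
anisotropic diffuse-scattering maps, scores them with symmetry- and
reproducibility-based correlation metrics, and fits phenomenological
models of correlated atomic motion.  This note records the models, the
numerical choices, and what the synthetic study conditions do and do not
demonstrate.

## Map construction

Each detector pixel at lab position (x, y, z_d) corresponds to a
scattering vector q = (s − s₀)/λ with |s| = |s₀| = 1, so |q| = 2 sin θ/λ
= 1/d (Å⁻¹).  Model formulas that need the angular-frequency convention
use q_rad = 2π|q| and say so at the point of use.  Fractional Miller
indices follow from the indexing matrix A (reciprocal cell vectors as
columns, lab frame) and the spindle rotation R_φ: hkl = (R_φ A)⁻¹ q.

Image pre-processing, in fixed order:

1. **Static masking** — user regions plus pixels with raw counts ≤ 0 or
   > 10 000 (saturation default).
2. **Windowed outlier rejection** — pixels more than 5 sd from their
   11×11 window mean (mask-aware moments; truncated windows at borders;
   the center pixel is included; zero-sd windows mask nothing).
3. **Background subtraction** — the paired non-crystal exposure, scaled
   by the exposure-time ratio, subtracted frame by frame.  Negative
   results are retained so merging stays unbiased.
4. **Geometric corrections** — intensities are divided by the product of
   the polarization factor f(1 − (ŝ·x̂)²) + (1 − f)(1 − (ŝ·ŷ)²) (f =
   horizontally polarized fraction, default 0.99; f = 0.5 reproduces the
   unpolarized Thomson form), the flat-detector solid-angle factor
   cos³θ_pix, and the relative sensor efficiency
   (1 − e^(−t/(ℓ cos θ)))/(1 − e^(−t/ℓ)) with sensor thickness t =
   0.32 mm and attenuation length ℓ = 0.55 mm by default (silicon at
   16 keV, E³-scaled from tabulated 8 keV values; both configurable).
   Pixel positions are first pulled back by the parallax displacement
   t_eff tan θ with t_eff = ℓ(1 − (1 + t/ℓ)e^(−t/ℓ))/(1 − e^(−t/ℓ)).
   Pixels whose polarization factor falls below a floor (default 0.01)
   are masked, not divided.
5. **Bragg cleaning** — pixels whose fractional indices all lie within
   0.25 of integers are masked (default) or replaced by the 11×11
   median of unflagged pixels; the merge step additionally rejects the
   0.5³ reciprocal-space box around every integer point regardless.
6. **Scaling and radial-variance removal** — each frame is scaled to the
   first frame of the series by least-squares matching of radial
   intensity profiles (s = ⟨p_f, p_ref⟩/⟨p_f, p_f⟩); alternative scale
   sources (mean intensity in the 5–1.82 Å water ring, overall mean,
   imported Bragg scale factors) are selectable.  The matrix of scaled
   radial profiles (200 uniform |q| bins to the resolution cutoff by
   default) is then mean-centered across frames and the projection of
   each row onto the three leading principal components is subtracted
   from the frame's pixels, interpolated linearly between bin centers
   (nearest-bin available).  The mean profile is retained; the isotropic
   component proper is removed later in reciprocal space.

Merging bins each surviving pixel into the voxel of its rounded Miller
indices on an integer-sampled grid (default 121³, hmax = 60; odd sizes
so the origin voxel exists), accumulating sums and counts.  Friedel
symmetrization averages inversion-related voxels; Laue symmetrization
averages the four-member 2/m orbit (unique axis b).  Orbit averages are
count-weighted, which equals pooling the underlying pixel observations.
Voxel |q| uses the reciprocal metric tensor, so monoclinic cells are
handled exactly.

**Isotropic subtraction.**  The radial average is estimated on |q|
shells (100 uniform shells spanning the grid by default), interpolated
linearly in |q| to each voxel, and subtracted; a second exact pass
removes each shell's residual count-weighted mean.  The interpolation
avoids ring artifacts; the exact pass guarantees that every shell's
observation-weighted mean is zero to machine precision, which the
downstream correlation metrics assume.

## Quality metrics

All metrics are centered Pearson correlations over voxels observed in
both operands, overall and in 15 equal-reciprocal-volume shells to
1.4 Å by default.  CC_Friedel and CC_Laue correlate the unsymmetrized
anisotropic map with its own symmetrized version; because every
symmetrized voxel contains the original voxel, an i.i.d. random map
scores 1/√m for orbit size m (≈ 0.707 for Friedel pairs, 0.50 for 2/m)
— these metrics flatter noise.  CC_1/2 randomly splits the observed
orbit members of each symmetry-unique voxel into halves and correlates
the half means (voxels with fewer than two observed members are
excluded; the split is per unique voxel, seeded).  CC_Rep is the mean
pairwise correlation between Laue-symmetrized anisotropic maps of
replicate crystals; CC_Cross is the same statistic against a different
crystal form.  Undefined shells are reported as missing, never zero.

## Diffuse models

Reference (Bragg) intensities are squared structure factors evaluated at
every integer grid point with four-Gaussian IT92 form factors, for the
full unit cell (space-group operators applied to positions and, in the
Cartesian convention, to U tensors), under three ADP treatments: zero
(T = 1), isotropic (T = exp(−B_eq|q|²/4), B_eq = (8π²/3) tr U), and
anisotropic (T = exp(−2π² qᵀUq), Cartesian q).  Multiple conformers are
reduced to the A conformer with occupancies reset to one.  Hydrogens
are included when present in the model.  No bulk-solvent model is
applied, so model-data comparisons exclude d > 10 Å.

The liquid-like motions (LLM) model takes atomic displacement
correlations decaying as exp(−r/γ); its 3D Fourier transform is the
kernel Γ_γ(q) = 8πγ³/(1 + γ²q_rad²)².  With zero individual ADPs the
diffuse intensity is σ²q_rad² e^(−σ²q_rad²) [I₀ ∗ Γ_γ]; with individual
ADPs retained, the overall Debye–Waller factor is replaced by unity and
I₀ by I_B, making σ a pure scale factor.  Convolution is circular on
the periodic grid by FFT with the kernel normalized to unit sum.  The
independent rigid-body translation (RBT) model is
I₀(q)(1 − e^(−σ²q_rad²)), with no convolution.  Model maps are
Laue-symmetrized and isotropic-subtracted exactly like data maps before
any comparison.

**Fitting.**  Parameters maximize the Pearson correlation with the data
map by Powell search, multi-started from the 3×3 grid σ ∈ {0.2, 0.4,
0.8} Å × γ ∈ {4, 8, 16} Å with bounds σ ∈ [0, 3] Å, γ ∈ [0.5, 100] Å
and tolerance 1e-4 on the correlation.  Because the correlation is
scale-free, the objective drops the σ² prefactor in the individual-ADP
form, which keeps the σ → 0 limit well defined (the σ-consistency
diagnostic asks whether σ refines toward zero when individual ADPs are
retained).

**Voxel-averaged forward model.**  A merged voxel is the average of the
continuous diffuse intensity over the 0.5³ acceptance box minus the
central Bragg-exclusion box, not a point sample at the node.  Fitting a
point-sampled model to merged maps biases γ low by roughly 20% under
the standard synthetic conditions.  `fit_model(..., voxel_average=True)`
therefore replaces the kernel with its quadrature average over the
acceptance region (a 4³ offset grid with Bragg-box points dropped);
this is exact up to the slowly varying prefactor because box-averaging
commutes with the convolution.  It is recommended whenever the data are
merged voxel averages; fits to integer-sampled volumes use the plain
kernel.

**ADP utilities.**  B_eq = (8π²/3) tr U; the anisotropy ratio is
λ_min/λ_max of U (1 = isotropic; non-positive-definite tensors are
flagged and clipped).  Difference anisotropic scale matrices are made
traceless (subtracting tr/3 from the diagonal) before being added to
every U tensor — converted from the B to the U convention by 1/8π² — so
every atom's B_eq is preserved exactly; non-PSD results are reported,
never fatal.

## Synthetic study conditions

The generator defines the conditions under which the package is
validated.  The toy crystal is monoclinic P2₁ (cell 40 × 42 × 44 Å,
β = 95°) with 32 pseudo-atoms whose anisotropy ratios center on 0.45,
the bell-shaped distribution typical of refined protein models, and
B_eq in 8–20 Å².  Ground truth is an LLM volume with σ* = 0.4 Å,
γ* = 7 Å on a 61³ grid (hmax = 30 reaches 1.4 Å), computed at 2×
oversampling: Bragg-node intensities are placed at integer positions
and convolved with the continuous kernel on the fine grid, so Ewald
slices sample the physically meaningful continuous intensity rather
than its integer samples.

Frames (512² pixels, 360 × 0.5°, 0.3 s crystal / 1 s background
exposures) are rendered by trilinear Ewald-slice interpolation, plus an
isotropic background (air-scatter decay, a water-ring hump near 3.3 Å,
and a flat floor; level 600 vs 150 for the diffuse signal, echoing
experiments where the isotropic component dwarfs the anisotropic one), a
lab-fixed azimuthal background modulation (amplitude 0.5 — capillary
and mount shadowing, identical in the paired background exposure), a
per-frame drift of the background shape in the crystal exposures
relative to their paired background exposures (sd 0.1 — beam and
capillary instability; this is what the radial-variance removal step
exists to absorb), Bragg spikes at integer indices,
polarization/solid-angle/absorption modulation, parallax displacement,
Poisson noise, and static dead/hot pixels.  Every generator output is
deterministic per seed; replicates share the crystal model but draw
independent orientations, artifacts and noise.

The contamination amplitudes were fixed in one calibration round so
that each prescribed quality degradation is visible: omitting
background subtraction, polarization correction, or radial-variance
removal each lowers CC_Rep on replicate pairs, while the three
profile-based scale methods still agree (CC > 0.99 between variants)
when variance removal is on.  These sign margins depend on the
contamination regime — with a much stronger per-frame drift the
per-image scale itself becomes ambiguous and the scale methods diverge;
with much weaker contamination the variance-removal step can cost more
signal than it removes noise.  The aligned-axis demonstration (omitting
the polarization correction raising CC_1/2 while lowering CC_Rep)
orients the crystal 2-fold axis along the spindle/polarization axis,
where the uncorrected polarization artifact mimics the crystal symmetry.

What passing these tests does **not** show about real data: the
generator has no detector point spread, no per-panel gains, no
absolute-intensity physics, a single mosaic-free orientation per frame,
and backgrounds far smoother than real capillary scatter; trilinear
slicing sets a smoothing floor on recovery accuracy (the exact identity
path uses nearest-voxel sampling instead, isolating the pipeline's
bookkeeping from the generator's interpolation).

## Problem sizes used in validation

Full-scale validation runs 512² × 360 frames onto the 61³ grid
(completeness 100%, map-truth correlation ≈ 0.98, through-stack
recovery σ ≈ 0.40 Å, γ within 7% of truth with the voxel-averaged
kernel).  The ablation study runs replicate pairs at 256² × 120 frames
to 2.6 Å (33³ grid), where the background contamination concentrates;
the aligned-polarization study needs the full 1.4 Å range and runs at
384² × 180 frames.  Direct-volume parameter recovery (5% noise) is at
61³.  These sizes are the package's standard desk-scale conditions;
all are configurable.

## Known limitations

Only the −1 and 2/m Laue groups are implemented (the 2/m orbit assumes
the unique axis is b).  Production metrics use integer sampling; finer
sampling is supported for visualization only.  Bragg-intensity scaling
is imported, never computed.  Rigid-body rotations and inter-molecular
coupled motions are out of scope, as is refinement of coordinates or
per-atom ADPs against diffuse data.  CBF frame input is not supported;
frames are read from HDF5 stacks or TIFF files.
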