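# Methods

## The recovery model

A vendor anatomic–metabolic snapshot is modelled as an exact composite:
achromatic pixels (HSV saturation < 0.10, configurable) carry the
grayscale anatomy, saturated pixels carry the metabolic overlay. The
overlay encodes a *normalized* ratio u ∈ [0, 1] through the color table's
hue channel; u = 1 corresponds to the per-slice maximum of Cho/NAA and is
rendered red. Because the vendor's exact table is not published, the
default table is a linear hue ramp from 240° (u = 0, blue) to 0°
(u = 1, red); any strictly monotone piecewise-linear (u, hue) table can be
supplied as YAML, and the inversion is the exact piecewise-linear inverse.
Hues within 10° below the 360° wrap point are treated as red, since red
sits on the circular seam and 8-bit rounding can land on either side.

Absolute calibration is external by design: the per-slice maxima are
scalar sidecar inputs (in the clinical workflow they come from the
scanner console), and ratio = u · max_s. Global normalization is therefore
nothing more than applying each slice's own calibration, which places all
slices on a single absolute Cho/NAA scale; the global maximum is the
maximum over slice maxima. A rescaled-to-global-max view is trivially
available (`values / global_max`), but the absolute scale is canonical —
it is what the ≥ 2.00 threshold is defined on.

Per CSI voxel, the hue of its overlay pixels is summarized by the median,
which is insensitive to anti-aliased block edges; a voxel with no overlay
pixels is flagged rejected and carries a missing value (never zero — zero
is a legal ratio).

## Interpolation and segmentation

The recovered 16×16×8 ratio field is interpolated bilinearly in-plane
between CSI voxel centers (with constant extrapolation over the outer
half-voxel of the box) and treated as constant through-plane within each
25 mm slab: the slab thickness is an order of magnitude larger than the
anatomical slice spacing, and inter-slab interpolation would invent axial
gradients the acquisition cannot resolve. Outside the CSI box the field
is missing; missing CSI voxels contaminate every interpolated value they
would influence. Bilinear interpolation is a convex combination, so the
interpolated field never overshoots the local data range.

Thresholding (Cho/NAA ≥ 2.00) is applied *after* interpolation: the
threshold is defined on ratios, and thresholding the continuous field
yields sub-voxel ROI boundaries. The reverse order (threshold on the CSI
grid, then resample the block mask) is available via
`segment_ratio_map(..., threshold_first=True)` for comparison.

## The synthetic phantom

The phantom emulates the study conditions end-to-end with known ground
truth:

* **Geometry.** CSI: 100×100 mm² FOV, 16×16 matrix, eight 25.0 mm slabs
  (6.25×6.25×25.0 mm³ ≈ 1 cm³ voxels). Anatomical MR at 0.90×0.90×3.00 mm,
  planning CT at 0.98×0.98×2.50 mm, both over a 180×180×225 mm³ head FOV.
* **Anatomy.** A head/brain ellipsoid pair with skull shell, ventricles,
  brainstem and optic chiasm; an enhancing lesion and surrounding edema as
  anisotropic Gaussians (masks by thresholding the smooth fields, so
  interpolation is exercised on differentiable data). CT and MR assign
  different intensities to the same underlying tissue fields.
* **Metabolic truth.** Cho/NAA = 0.4 background plus a Gaussian
  abnormality (σ = 16×14×30 mm, peak 2.65) centered on a slab boundary and
  offset from the enhancing lesion — metabolically active tissue need not
  coincide with contrast enhancement. With the default geometry, slice
  maxima straddle the 2.00 threshold bimodally (two slabs ≈ 2.4, the rest
  ≤ 1.4), mirroring the clinical pattern where slices either clearly pass
  or clearly fail.
* **Ground truth at anatomical resolution** honors the acquisition
  geometry: continuous in-plane, evaluated at each slab's center plane and
  constant through-plane. Comparing a slab-resolution reconstruction
  against sub-slab truth would test information the data cannot contain.
* **Rejection.** Voxel-quality rejection is simulated as independent
  Bernoulli draws (default p = 0.15) restricted to the outer ring of each
  CSI slice, mimicking lipid/bone contamination at the box boundary.
* **Composites.** Overlay blocks are solid (opacity 1) 6.25 mm squares
  resampled to the anatomical pixel grid, full saturation and value, over
  an 8-bit grayscale underlay; the only degradation is 8-bit quantization.
  The snapshot convention (block layout, no grid lines) is one documented
  choice among several plausible vendor styles.
* **Texture.** Both modalities share a smooth random blob field
  (36 Gaussians, σ = 9 mm, seeded) with modality-specific amplitudes large
  enough to register against a 32-bin joint histogram. This emulates the
  information content of real anatomy; a bare ellipsoid phantom is almost
  rotationally symmetric in-plane and would make in-plane rotation
  ill-determined in a way real heads are not.

What the phantom does **not** model: MR physics (no k-space, no spectra,
no B0/B1 inhomogeneity), partial-volume and chemical-shift displacement
of the CSI grid, overlay anti-aliasing or transparency, patient motion.
Passing tests therefore demonstrate correctness of the *processing* chain
under ideal composites, not robustness to vendor-specific rendering.

## Registration QC

Rigid CT↔MR fusion uses Mattes mutual information (32 bins, 20 % random
sampling, seeded) on a 3-level multi-resolution pyramid with a
regular-step gradient-descent optimizer and physical-shift parameter
scaling (SimpleITK). The metric is evaluated inside an Otsu foreground
mask of the fixed image: the air background is an exact constant in both
modalities, and including it leaves the rotational axes of the metric
dominated by histogram artifacts (empirically the aligned pose was not
the optimum without the mask).

The consistency analysis registers each case `repeats` times (default
10), each run starting from an independently perturbed initialization
(uniform ±2 mm / ±2°, seeded); what varied between repeated clinical
co-registrations is not recorded, so perturbed initialization is the
chosen surrogate. Statistics per case and parameter are the population
SD (divide by n — the repeats are the complete set of interest) and the
max–min range; headline numbers are their means across cases. Rotation
parameters are fixed-axis Euler angles in the underlying toolkit's Z·X·Y
composition about the fixed image's physical center; the convention
string travels with every serialized transform.

The acceptance experiment (`scripts/acceptance.py`) uses 4 cases × 10
repeats with anatomy resampled to 1.8×1.8×3.0 mm and CT to
1.96×1.96×2.5 mm — half the in-plane sampling of the defaults, chosen so
the whole experiment is a few minutes on one CPU while leaving the
repeatability statistics essentially unchanged (the spread is governed by
optimizer convergence, not by in-plane sampling density).

## Target volumes and dosimetry

"GTV + margin including structure X" is read as (GTV ⊕ margin) ∪ X — the
named structure must end inside the CTV regardless of its distance from
the GTV. Expansions threshold the exact Euclidean distance transform
computed in physical units, which is correct under anisotropic voxels
(unlike iterated structuring elements). No anatomical-barrier clipping is
applied by default (clinical practice varies and the source workflow does
not state it); a `clip_to` mask is available. Expansion is clipped at the
grid edge with a warning.

Volumes are voxel-center counts × voxel volume, with no partial-volume
weighting — the convention of TPS-style DVHs and exactly reproducible by
counting. The DVH is cumulative with 0.1 Gy default bins, but point
metrics (D1%, Vx, I₁/I₂) are computed from the raw voxel doses, so bin
width only affects the reported curve. D1% is the quantile-style
near-maximum: the smallest dose such that at most 1 % of voxels lie at or
above it (for a uniform structure this is the uniform dose). I₂ and CN
are flagged undefined when no voxel reaches 95 % of prescription.
V18/V36/V50 are reported relative to normal brain = brain − PTV1;
whether clinical denominators excluded the PTV is not stated, so the
exclusion is configurable through which mask the caller passes.

Paired plan comparisons use the two-sided Wilcoxon signed-rank test with
zero differences dropped; the exact null distribution is used for ≤ 25
informative pairs and the normal approximation with continuity correction
above. Fewer than 3 informative pairs is a no-test error.

The phantom dose model places the prescription inside each PTV with an
isotropic Gaussian falloff of the distance to the target surface
(default width 12 mm; width 0 gives the degenerate step plan whose
coverage metrics are exactly 1). Overlapping prescriptions resolve to
the voxel-wise maximum. This is deliberately an idealized dose — beam
modelling and optimization are TPS functions outside scope — but it has
exactly computable DVH/conformity values, which is what the metric code
is tested against.

## DICOM conventions

LPS patient coordinates, 0-based voxel indices, positions at voxel
centers. Scalar series are written as signed 16-bit with rescale tags;
composites as 8-bit interleaved RGB secondary capture. Header
transplantation deep-copies the source dataset (so patient, study, frame
of reference and geometry tags are byte-identical), replaces the pixel
module, marks the image DERIVED\SECONDARY and regenerates the SOP and
series instance UIDs — copying instance UIDs would corrupt a TPS
database, and the `HeaderTransplantSpec` type refuses configurations
that try. `read_series` rejects mixed directories, missing geometry tags
and irregular slice spacing rather than guessing.

## Numerical choices and edge cases

* Hue inversion tolerance: 1.5° snap at the table ends (covers endpoint
  quantization); beyond that, out-of-gamut is an error, not a clamp.
* 8-bit round-trip error bound: at full saturation/value the hue
  resolution is 60/255 degrees, i.e. Δu = (60/255)/240 for the default
  table; the render→recover tests assert this bound exactly.
* Rejected/missing voxels propagate as NaN and are excluded from maxima,
  masks and DVHs; masks store missing as False.
* A slice whose maximum is missing or ≤ 0 renders with no overlay and is
  flagged; calibrating against it is an error only if it has accepted
  voxels.
* Degenerate registration inputs (no physical overlap) and ragged repeat
  counts are errors; optimizer iteration-cap stops produce warnings.

## Known limitations

* The color model assumes the overlay is fully saturated and opaque;
  alpha-blended vendor renderings would bias recovered hues and need a
  saturation-dependent correction.
* Through-plane constancy means ROI boundaries are exact slab boundaries
  axially; axial partial-volume at slab edges is not modelled.
* The registration consistency analog measures repeatability of a
  correctly converged optimum on synthetic images; it does not probe
  failure modes of real multi-modal registration (truncated FOV, metal,
  motion).
* Dose grids are synthetic; conformity statistics on phantom plans
  characterize the metric implementations, not achievable plan quality.
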