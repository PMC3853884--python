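# Methods

This note documents the model behind `cbctprior`, the choices made where
the design was genuinely open, and what the synthetic phantom does and
does not establish about real scans.

## Correction model

The correction assumes the CBCT differs from the (rigidly aligned)
planning CT by a *smooth, multiplicative* field on the attenuation scale,
different per tissue class, plus voxel noise. Writing
μ = (HU + 1000)/1000 — so air is 0, water is 1 — the model is

    μ_CBCT(x) ≈ b_c(x) · μ_CT(x) + noise,   x in class c,

with b_c smooth at the several-centimetre scale of scatter cupping. The
per-class ratio image R_c = μ_CT / μ_CBCT is then an estimate of 1/b_c
corrupted by anatomy mismatch and noise; low-pass filtering it keeps the
artifact field and discards the rest, and multiplying the CBCT by the
filtered ratio inverts the artifact without touching the CBCT's own
high-frequency content (edges, treatment-day anatomy).

Working on μ rather than raw HU is essential: HU cross zero at air, so
the voxelwise quotient of two HU images is ill-defined, while on the
attenuation scale the quotient is exactly the positive multiplicative
artifact factor. The μ offset (1000 HU) is configurable
(`FilterSpec.mu_offset_hu`).

Per-class estimation (rather than one global ratio) matters because the
CBCT bias is tissue-dependent and because a single smoothed ratio would
blur the lung/soft interface artifact into both classes. Filtering is
*mask-normalized* (normalized convolution): smooth(w·R)/smooth(w) with w
the defined-voxel indicator, evaluated with zero-padding, so values never
leak across class boundaries and constants are preserved exactly.

### Which mask where

Two segmentations exist (CT and CBCT). The package uses:

* the **joint** mask (CT class ∩ CBCT class ∩ FOV) for ratio
  *estimation* — only voxels both images agree on carry information
  about b_c;
* the **CBCT** masks for *recombination* — the corrected image must keep
  the anatomy of the day, and the CBCT segmentation is where that
  anatomy lives.

If a class present in the CBCT has an empty joint mask (e.g. no bone in
a small FOV overlap), its ratio field falls back to the soft-tissue mean
ratio: soft tissue is always present and its ratio is the best available
single-number surrogate.

### Numerical guards

* Ratios are clamped to [0.2, 5.0] *before* smoothing: residual
  misregistration at class interfaces pairs voxels of different tissues,
  and a handful of extreme quotients would otherwise dominate the local
  estimate.
* The denominator is floored at μ = 1e-3. Voxels where **both** images
  are below that air level are excluded from the estimation mask
  entirely: an air/air quotient is noise over noise and estimates
  nothing. This exclusion is also what makes the identity property exact
  — with CBCT = CT the ratio is 1 on every defined voxel, so the
  corrected image reproduces the input to machine precision.
* Where the smoothed mask weight underflows (isolated defined islands),
  the field falls back to the defined-region mean.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `FilterSpec.width_mm` | 20 mm FWHM | low-pass cutoff; must sit between anatomy (< 1 cm) and scatter scale (several cm) |
| `FilterSpec.ratio_floor/ceiling` | 0.2 / 5.0 | clamp on the per-voxel ratio |
| `SegmentationThresholds.lung_upper_hu` | −400 HU | lung/soft boundary inside the body |
| `SegmentationThresholds.bone_lower_hu` | +200 HU | soft/bone boundary |
| `SegmentationThresholds.body_threshold_hu` | −500 HU | body outline |
| `SegmentationThresholds.min_component_mm3` | 500 mm³ | lung/bone specks below this are folded into soft |

The HU thresholds are standard thoracic ranges, exposed as configuration
because they are empirical, not physical. External air is separated from
lung by the body mask, not by HU — both are low-HU, and the distinction
is topological. Low-HU pockets inside the body (bowel/airway gas) land
in the lung class, which is attenuation-equivalent handling; components
below the volume floor become soft tissue.

The body mask is the largest connected component above the body
threshold, morphologically closed (ball, radius 3 voxels) and hole-filled
per axial slice. Closing and erosion are computed on an edge-replicated
padding of the volume: anatomy running through the image boundary (a
trunk crossing the scan's first/last slice) must not be eroded by the
filter's implicit background border.

## Registration

Mutual information (Mattes, 50 bins) is the default metric because the
CBCT's HU bias is exactly what the pipeline later removes — least-squares
metrics would chase it. Multi-resolution (shrink 4/2/1), regular-step
gradient descent, 10 % random metric sampling at a fixed seed,
initialized by aligning the body-mask centers of mass (robust to FOV
truncation). ITK is forced to a single work unit inside `register_rigid`
so identical seeds give bit-identical transforms; a clinically supplied
transform file bypasses the module entirely. Transforms are Euler Z–Y–X
(degrees) about an explicit center, serialized as a 9-number text record;
both 6-DOF and translation-only (3-DOF) records are accepted.

## The digital phantom and degradation

The phantom emulates a thorax/breast planning CT: an elliptic trunk of
soft tissue (+40 HU), two lung ellipsoids (−750 HU), a spinal column and
rib spheres (+700 HU), and a hemi-ellipsoidal breast protrusion, on a
128×128×64 grid at 2.5 mm. Tissue classes carry 20 HU Gaussian texture;
exterior air is exactly −1000 HU with no texture — air in a CT sits at
the floor of the HU scale, and symmetric texture around −1000 would be
half-clipped by the attenuation-scale clamp, biasing every class-mean
contract. The grid size keeps a full pipeline run at a few seconds while
leaving ≈ 50 voxels across each lung, enough for the mask-normalized
filter to be meaningfully local.

The degradation applies, on the μ scale: a radial cupping field
1 − A·exp(−(r/L)²) with A = 0.15, L = 80 mm (darker core, recovering
rim); a smooth angular shading bump (amplitude 0.05) centered on the
unscanned 160° sector of a 200° arc; per-class HU shifts (lung −30,
soft −40, bone −60); additive 15 HU Gaussian noise; and truncation to a
100 mm-radius cylindrical FOV (≈ 70 % of the 140 mm body half-width).
The realized multiplicative factor (everything except noise and
truncation) is stored as ground truth, so tests can score the correction
against the exact field that was applied. The partial arc is represented
only as this shading surrogate — no projection-space reconstruction is
simulated, so streaks, view aliasing, and truncation-edge reconstruction
artifacts of real limited-arc CBCT are absent.

What passing the phantom tests therefore shows: the pipeline removes
smooth multiplicative/per-class bias, is exact under identity and
outside the FOV, does not amplify noise, and its registration recovers
rigid offsets under that bias. What it does not show: robustness to
deformable anatomy change, reconstruction streaks, metal, or
segmentation thresholds on pathological tissue — on real scans those are
the risks to validate separately.

## Field-of-view handling

The valid-data mask of a CBCT is taken to be the voxels not exactly equal
to the padding value (−1000 HU); reconstructed voxels, even air, deviate
from it through noise. For data where this heuristic fails, an explicit
FOV mask can be passed to `correct_cbct`. On the planning-CT grid the
FOV is additionally intersected with the resampling support. Lung/bone
labels are suppressed (demoted to soft) in a 2-voxel ring at the FOV
boundary, where partial-object truncation makes class transitions
spurious; outside the FOV the corrected image is a verbatim copy of the
planning CT, so the completion is exact by construction.

## Evaluation

* **Histograms**: 10 HU bins from −1100 to +1500 HU, open-ended end
  bins, compared on frequencies (masks of different sizes must be
  comparable); L1, χ², and 1-D earth-mover distances.
* **HU errors**: MAE/RMSE over body ∩ FOV plus per-class signed means
  against ground-truth masks.
* **WEPL**: HU → relative electron density through a fixed
  piecewise-linear calibration (−1000→0.001, −750→0.25, 0→1.0, 200→1.10,
  700→1.43, 1500→1.85), then trapezoidal line integrals at 1 mm steps
  along anterior→posterior parallel rays, 5 mm apart, over rays crossing
  the body. WEPL is the image-level quantity dose engines consume, so
  per-ray WEPL discrepancies replace treatment-planning-system dose
  endpoints at desk scale. The integrator converges well under 0.5 % on
  step halving.

## Known limitations and edge behaviour

* A global attenuation rescale of the CBCT is absorbed by the ratio
  fields almost everywhere (mean change ≈ 0.002 HU on the standard
  phantom), but a rescale also moves voxels across the fixed HU
  segmentation thresholds; the < 0.1 % of boundary voxels that change
  class can shift by ~10 HU because a different class's smoothed field
  applies there.
* Resampling the CBCT to the planning-CT grid is linear interpolation;
  at 2.5 mm voxels this blurs high-contrast interfaces and dominates the
  residual error after correction (the correction itself neither can nor
  should sharpen it).
* The correction is multiplicative and low-frequency by design: it
  cannot repair high-frequency artifacts (streaks, rings), and inside a
  class it transfers no anatomy from the CT — a genuine anatomical
  change on the day appears in the corrected image unaltered, which is
  the intended behaviour for dose verification.
* The 200° arc surrogate and the cylinder FOV are idealized; real
  truncation produces bright reconstruction rims that the FOV edge-ring
  suppression only partially models.
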