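"""Prior-CT ratio-image CBCT correction.

The algorithm estimates, per tissue class, the smooth multiplicative field
relating the planning CT to the CBCT, and multiplies the CBCT by it:

1. resample the CBCT onto the planning-CT grid through the rigid transform;
2. segment both images into air / lung / soft tissue / bone;
3. per class, form the voxelwise ratio planning-CT / CBCT on the
   attenuation-proportional scale mu = (HU + 1000) / 1000 over the voxels
   both segmentations agree on;
4. low-pass filter each ratio field (mask-normalized smoothing, so values
   never leak across class boundaries);
5. multiply the CBCT by the filtered ratio of its own class;
6. recombine the four enhanced parts using the CBCT masks — the anatomy
   of the day;
7. complete the truncated field of view from the planning CT.

The ratio is computed on the mu scale rather than raw HU because HU cross
zero at air, which would make the voxelwise quotient ill-defined; on the
attenuation scale the quotient is the (positive) multiplicative artifact
field itself. Ratios are clamped to [ratio_floor, ratio_ceiling] before
smoothing so residual misregistration at class interfaces cannot dominate
the local estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .segmentation import (
    CLASS_NAMES,
    SegmentationThresholds,
    TissueMaskSet,
    segment_image,
)
from .volume_io import (
    CbctPriorError,
    ImageGrid,
    IntensityUnit,
    RigidTransform,
    VolumetricImage,
    resample_to_grid,
)

__all__ = [
    "FilterSpec",
    "MaskedRatio",
    "CorrectionResult",
    "hu_to_mu",
    "mu_to_hu",
    "estimate_fov_mask",
    "compute_ratio_field",
    "smooth_ratio_field",
    "enhance_part",
    "correct_cbct",
]

#: below this mu value a voxel is effectively air; denominators are floored
#: here and air/air quotients are treated as undefined
MU_EPSILON = 1e-3

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class CorrectionError(CbctPriorError):
    """Correction pipeline failure (empty overlap, degenerate inputs)."""


@dataclass(frozen=True)
class FilterSpec:
    """Ratio-field filtering parameters.

    ``width_mm`` is the FWHM of the Gaussian (or the window edge of the
    median filter). 20 mm keeps anatomy while passing the several-cm
    scatter/cupping scale. ``mu_offset_hu`` defines the attenuation scale
    mu = (HU + offset) / offset on which the ratio is formed.
    """

    kind: str = "gaussian"
    width_mm: float = 20.0
    ratio_floor: float = 0.2
    ratio_ceiling: float = 5.0
    mu_offset_hu: float = 1000.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "median"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.width_mm <= 0:
            raise ValueError("width_mm must be > 0")
        if not (0.0 < self.ratio_floor < 1.0 < self.ratio_ceiling):
            raise ValueError("need 0 < ratio_floor < 1 < ratio_ceiling")
        if self.mu_offset_hu <= 0:
            raise ValueError("mu_offset_hu must be > 0")


def hu_to_mu(img: VolumetricImage, mu_offset_hu: float = 1000.0) -> VolumetricImage:
    """Map HU to the attenuation-proportional scale, clamped at zero.

    mu = (HU + offset) / offset, so air (-1000 HU) maps to 0 and water
    (0 HU) to 1 at the default offset.
    """
    if img.unit is not IntensityUnit.HU:
        raise ValueError(f"expected an HU image, got {img.unit}")
    mu = np.clip((img.voxels + mu_offset_hu) / mu_offset_hu, 0.0, None)
    return img.copy_with(mu, unit=IntensityUnit.MU_RELATIVE, padding_value=0.0)


def mu_to_hu(img: VolumetricImage, mu_offset_hu: float = 1000.0) -> VolumetricImage:
    """Inverse of :func:`hu_to_mu` for non-negative mu."""
    if img.unit is not IntensityUnit.MU_RELATIVE:
        raise ValueError(f"expected a MU_RELATIVE image, got {img.unit}")
    hu = img.voxels * mu_offset_hu - mu_offset_hu
    return img.copy_with(hu, unit=IntensityUnit.HU, padding_value=-1000.0)


def estimate_fov_mask(cbct: VolumetricImage) -> np.ndarray:
    """Voxels carrying reconstructed data rather than the padding value.

    Truncated scanners cut the volume to the padding value exactly; any
    reconstructed voxel (even air) deviates from it through noise. Supply
    an explicit FOV mask instead when this heuristic does not hold.
    """
    return cbct.voxels != cbct.padding_value


@dataclass
class MaskedRatio:
    """A ratio field defined only on a voxel subset."""

    values: np.ndarray
    defined: np.ndarray

    def defined_mean(self) -> float:
        if not self.defined.any():
            raise ValueError("ratio field has no defined voxels")
        return float(self.values[self.defined].mean())


def compute_ratio_field(ct_mu: VolumetricImage, cbct_mu: VolumetricImage,
                        class_mask: np.ndarray, spec: FilterSpec | None = None
                        ) -> MaskedRatio:
    """Voxelwise planning-CT / CBCT ratio over one class mask (mu scale).

    The denominator is floored at ``MU_EPSILON`` and the quotient clamped
    to [ratio_floor, ratio_ceiling]. Voxels where *both* images are below
    the air level are flagged undefined: an air/air quotient estimates
    nothing and would only pollute the smoothed field.
    """
    spec = spec or FilterSpec()
    if ct_mu.unit is not IntensityUnit.MU_RELATIVE or cbct_mu.unit is not IntensityUnit.MU_RELATIVE:
        raise ValueError("ratio inputs must be MU_RELATIVE images")
    if ct_mu.grid.shape != cbct_mu.grid.shape:
        raise ValueError("ratio inputs must share a grid")
    class_mask = np.asarray(class_mask, dtype=bool)
    a, b = ct_mu.voxels, cbct_mu.voxels
    defined = class_mask & ~((a < MU_EPSILON) & (b < MU_EPSILON))
    if not class_mask.any():
        warnings.warn("empty class mask: ratio field is entirely undefined",
                      stacklevel=2)
    values = np.ones(a.shape, dtype=np.float64)
    ratio = a / np.maximum(b, MU_EPSILON)
    values[defined] = np.clip(ratio[defined], spec.ratio_floor, spec.ratio_ceiling)
    return MaskedRatio(values=values, defined=defined)


def _sigma_voxels(width_mm: float, spacing: tuple[float, float, float]) -> tuple[float, ...]:
    return tuple(width_mm * _FWHM_TO_SIGMA / s for s in spacing)


def smooth_ratio_field(ratio: MaskedRatio, target_mask: np.ndarray,
                       grid: ImageGrid, spec: FilterSpec | None = None
                       ) -> np.ndarray:
    """Low-pass the ratio field and extend it over ``target_mask``.

    Mask-normalized (normalized-convolution) smoothing: the mask-weighted
    values and the mask weights are filtered separately and divided, so
    undefined voxels contribute nothing and values never bleed across the
    mask boundary. Regions the smoothed weight cannot reach are filled
    with the defined-region mean. Output is clamped to the ratio bounds
    and equals 1 outside ``target_mask``.
    """
    spec = spec or FilterSpec()
    target_mask = np.asarray(target_mask, dtype=bool)
    if not ratio.defined.any():
        raise ValueError("cannot smooth an entirely undefined ratio field")
    w = ratio.defined.astype(np.float64)
    f = np.where(ratio.defined, ratio.values, 0.0)
    if spec.kind == "gaussian":
        sigma = _sigma_voxels(spec.width_mm, grid.spacing)
        num = ndimage.gaussian_filter(f, sigma=sigma, mode="constant", cval=0.0)
        den = ndimage.gaussian_filter(w, sigma=sigma, mode="constant", cval=0.0)
    else:  # median: rank filter on the mean-filled field
        size = tuple(max(1, int(round(spec.width_mm / s)) | 1) for s in grid.spacing)
        filled = np.where(ratio.defined, ratio.values, ratio.defined_mean())
        num = ndimage.median_filter(filled, size=size, mode="nearest")
        den = np.ones_like(num)
    fallback = ratio.defined_mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        smoothed = np.where(den > 1e-6, num / np.maximum(den, 1e-300), fallback)
    smoothed = np.clip(smoothed, spec.ratio_floor, spec.ratio_ceiling)
    return np.where(target_mask, smoothed, 1.0)


def enhance_part(cbct_mu: VolumetricImage, smoothed_ratio: np.ndarray,
                 part_mask: np.ndarray) -> np.ndarray:
    """Multiply the CBCT by the filtered ratio on one class mask.

    Returns the enhanced mu values on ``part_mask`` and zero elsewhere;
    the caller sums the four parts (the masks partition the grid).
    """
    part_mask = np.asarray(part_mask, dtype=bool)
    return np.where(part_mask, smoothed_ratio * cbct_mu.voxels, 0.0)


@dataclass
class CorrectionResult:
    """Corrected CBCT plus everything needed to audit the run."""

    corrected: VolumetricImage
    ratio_fields: dict[str, VolumetricImage]
    masks_ct: TissueMaskSet
    masks_cbct: TissueMaskSet
    transform: RigidTransform
    fov: np.ndarray
    config: dict[str, Any] = field(default_factory=dict)


def correct_cbct(ct: VolumetricImage, cbct: VolumetricImage,
                 transform: RigidTransform | None = None,
                 thresholds: SegmentationThresholds | None = None,
                 spec: FilterSpec | None = None,
                 fov_mask: np.ndarray | None = None) -> CorrectionResult:
    """Run the full ratio-image correction pipeline.

    Parameters
    ----------
    ct, cbct : VolumetricImage
        Planning CT and CBCT, both in HU. The CBCT may live on any grid.
    transform : RigidTransform, optional
        Maps CBCT world coordinates into CT world coordinates (e.g. from
        :func:`cbctprior.registration.register_rigid` or a clinical
        system). Identity when omitted.
    thresholds, spec : optional
        Segmentation thresholds and ratio-filter parameters.
    fov_mask : ndarray of bool, optional
        Valid-data mask on the *CBCT native* grid; estimated from the
        padding value when omitted.

    Returns
    -------
    CorrectionResult
        ``corrected`` lives on the planning-CT grid; voxels outside the
        field of view are copied verbatim from the planning CT.
    """
    thresholds = thresholds or SegmentationThresholds()
    spec = spec or FilterSpec()
    transform = transform or RigidTransform.identity()
    if ct.unit is not IntensityUnit.HU or cbct.unit is not IntensityUnit.HU:
        raise ValueError("correct_cbct expects HU images")

    # step 1: resample the CBCT onto the planning-CT grid
    cbct_on_ct, support = resample_to_grid(cbct, ct.grid, transform, "linear")
    if fov_mask is None:
        fov_native = estimate_fov_mask(cbct)
    else:
        fov_native = np.asarray(fov_mask, dtype=bool)
        if fov_native.shape != cbct.grid.shape:
            raise ValueError("fov_mask must be on the CBCT native grid")
    fov_img = VolumetricImage(grid=cbct.grid, voxels=fov_native.astype(np.float64),
                              unit=IntensityUnit.RATIO, padding_value=0.0)
    fov_on_ct, _ = resample_to_grid(fov_img, ct.grid, transform, "nearest")
    fov = (fov_on_ct.voxels > 0.5) & support
    if not fov.any():
        raise CorrectionError("CBCT support does not overlap the planning-CT grid")

    # step 2: segment both images with the same thresholds
    masks_ct = segment_image(ct, thresholds)
    masks_cbct = segment_image(cbct_on_ct, thresholds, fov=fov)

    # steps 3-5: per-class ratio estimation, filtering, enhancement
    ct_mu = hu_to_mu(ct, spec.mu_offset_hu)
    cbct_mu = hu_to_mu(cbct_on_ct, spec.mu_offset_hu)

    ratios: dict[str, MaskedRatio] = {}
    for name in CLASS_NAMES:
        joint = masks_ct.class_mask(name) & masks_cbct.class_mask(name) & fov
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratios[name] = compute_ratio_field(ct_mu, cbct_mu, joint, spec)

    # graceful fallback for classes absent from the joint mask: borrow the
    # soft-tissue mean ratio (soft tissue is always present in a body)
    if ratios["soft"].defined.any():
        soft_mean = ratios["soft"].defined_mean()
    else:
        soft_mean = 1.0

    corrected_mu = np.zeros(ct.grid.shape, dtype=np.float64)
    ratio_fields: dict[str, VolumetricImage] = {}
    for name in CLASS_NAMES:
        target = masks_cbct.class_mask(name) & fov
        if not target.any():
            ratio_fields[name] = VolumetricImage(
                grid=ct.grid, voxels=np.ones(ct.grid.shape), unit=IntensityUnit.RATIO)
            continue
        if ratios[name].defined.any():
            smoothed = smooth_ratio_field(ratios[name], target, ct.grid, spec)
        else:
            warnings.warn(
                f"class {name!r} has no joint CT/CBCT voxels; "
                "using the soft-tissue mean ratio", stacklevel=2)
            smoothed = np.where(target, soft_mean, 1.0)
        corrected_mu += enhance_part(cbct_mu, smoothed, target)
        ratio_fields[name] = VolumetricImage(grid=ct.grid, voxels=smoothed,
                                             unit=IntensityUnit.RATIO)

    # step 6 happened in the sum above (CBCT masks select each part);
    # step 7: complete the missing field of view from the planning CT
    corrected_img = mu_to_hu(
        VolumetricImage(grid=ct.grid, voxels=corrected_mu,
                        unit=IntensityUnit.MU_RELATIVE, padding_value=0.0),
        spec.mu_offset_hu,
    )
    out = corrected_img.voxels
    out[~fov] = ct.voxels[~fov]
    corrected = VolumetricImage(grid=ct.grid, voxels=out, unit=IntensityUnit.HU)

    config = {
        "thresholds": thresholds.__dict__.copy(),
        "filter": spec.__dict__.copy(),
        "transform": {
            "rotation_deg": transform.rotation_deg,
            "translation_mm": transform.translation_mm,
            "center_mm": transform.center_mm,
        },
    }
    return CorrectionResult(
        corrected=corrected,
        ratio_fields=ratio_fields,
        masks_ct=masks_ct,
        masks_cbct=masks_cbct,
        transform=transform,
        fov=fov,
        config=config,
    )
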