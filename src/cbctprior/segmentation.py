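"""Four-class HU segmentation: air, lung, soft tissue, bone.

The correction operates per tissue class, so an image must first be split
into four binary masks that partition the grid. External air is separated
from lung by a body mask (both are low-HU); inside the body, fixed HU
thresholds assign lung (< -400 HU), bone (> +200 HU), and soft tissue
(the remainder). Small lung/bone specks below a volume floor are folded
back into soft tissue, since isolated threshold noise would otherwise
produce meaningless per-class ratio estimates.

Thresholds are configurable: they are empirical, standard thoracic HU
ranges, not physical constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .volume_io import CbctPriorError, ImageGrid, VolumetricImage

__all__ = [
    "SegmentationThresholds",
    "TissueMaskSet",
    "SegmentationError",
    "compute_body_mask",
    "segment_tissues",
    "clean_masks",
    "suppress_fov_edge",
    "segment_image",
    "CLASS_NAMES",
    "CLASS_LABELS",
]

CLASS_NAMES = ("air", "lung", "soft", "bone")
CLASS_LABELS = {"air": 0, "lung": 1, "soft": 2, "bone": 3}


class SegmentationError(CbctPriorError):
    """Segmentation produced an empty or inconsistent result."""


@dataclass(frozen=True)
class SegmentationThresholds:
    """HU decision boundaries for the four-class split.

    ``lung_upper_hu``/``soft_lower_hu`` and ``soft_upper_hu``/``bone_lower_hu``
    are the two class boundaries (kept as separate named fields so config
    files read naturally); ``body_threshold_hu`` separates patient from
    surrounding air, and components of lung or bone smaller than
    ``min_component_mm3`` are reassigned to soft tissue.
    """

    lung_upper_hu: float = -400.0
    soft_lower_hu: float = -400.0
    soft_upper_hu: float = 200.0
    bone_lower_hu: float = 200.0
    body_threshold_hu: float = -500.0
    min_component_mm3: float = 500.0

    def __post_init__(self) -> None:
        if not (self.lung_upper_hu <= self.soft_lower_hu <= self.soft_upper_hu
                <= self.bone_lower_hu):
            raise ValueError("tissue thresholds must be ordered lung <= soft <= bone")
        if self.min_component_mm3 < 0:
            raise ValueError("min_component_mm3 must be >= 0")


@dataclass
class TissueMaskSet:
    """The four class masks plus body and field-of-view masks on one grid.

    Invariant: air/lung/soft/bone are pairwise disjoint and jointly cover
    every voxel (checked on construction).
    """

    grid: ImageGrid
    air: np.ndarray
    lung: np.ndarray
    soft: np.ndarray
    bone: np.ndarray
    body: np.ndarray
    fov: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fov is None:
            self.fov = np.ones(self.grid.shape, dtype=bool)
        for name in ("air", "lung", "soft", "bone", "body", "fov"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != self.grid.shape:
                raise ValueError(f"mask {name!r} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)
        self.validate_partition()

    def validate_partition(self) -> None:
        total = (self.air.astype(np.int8) + self.lung.astype(np.int8)
                 + self.soft.astype(np.int8) + self.bone.astype(np.int8))
        if not np.all(total == 1):
            bad = int(np.sum(total != 1))
            raise SegmentationError(
                f"class masks do not partition the grid ({bad} voxels covered != once)"
            )

    def class_mask(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def labelmap(self) -> np.ndarray:
        """Integer label volume: 0=air, 1=lung, 2=soft, 3=bone."""
        lab = np.zeros(self.grid.shape, dtype=np.uint8)
        for name, value in CLASS_LABELS.items():
            lab[self.class_mask(name)] = value
        return lab

    @classmethod
    def from_labelmap(cls, grid: ImageGrid, labels: np.ndarray,
                      body: np.ndarray | None = None,
                      fov: np.ndarray | None = None) -> "TissueMaskSet":
        masks = {name: labels == value for name, value in CLASS_LABELS.items()}
        if body is None:
            body = ~masks["air"]
        return cls(grid=grid, body=np.asarray(body, dtype=bool), fov=fov, **masks)

    def copy(self) -> "TissueMaskSet":
        return TissueMaskSet(
            grid=self.grid,
            air=self.air.copy(), lung=self.lung.copy(),
            soft=self.soft.copy(), bone=self.bone.copy(),
            body=self.body.copy(), fov=self.fov.copy(),
        )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(np.argmax(sizes))


def compute_body_mask(img: VolumetricImage, body_threshold_hu: float = -500.0,
                      closing_radius_voxels: int = 3) -> np.ndarray:
    """Patient outline: largest bright component, closed and hole-filled.

    Voxels above ``body_threshold_hu`` are thresholded, the largest
    connected component kept, morphologically closed with a ball of
    ``closing_radius_voxels``, and holes filled per axial (constant-z)
    slice so that lungs — axially open at the top and bottom of the scan —
    are still enclosed by the outline.
    """
    raw = img.voxels > body_threshold_hu
    if not raw.any():
        raise SegmentationError(
            f"no voxel above {body_threshold_hu} HU: cannot find a body"
        )
    body = _largest_component(raw)
    if closing_radius_voxels > 0:
        # pad with edge values so anatomy running through the volume
        # boundary is not eroded by the closing
        r = closing_radius_voxels
        padded = np.pad(body, r, mode="edge")
        padded = ndimage.binary_closing(padded, structure=ball(r))
        body = padded[r:-r, r:-r, r:-r]
    # fill internal holes slice by slice (axial = constant k along z axis)
    for k in range(body.shape[2]):
        body[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    return body


def segment_tissues(img: VolumetricImage, thresholds: SegmentationThresholds,
                    body: np.ndarray) -> TissueMaskSet:
    """Split an HU image into air/lung/soft/bone given a body outline.

    Outside the body everything is air; inside, HU below ``lung_upper_hu``
    is lung, above ``bone_lower_hu`` is bone, and the remainder soft
    tissue. Specks below the volume floor are then folded into soft.
    """
    body = np.asarray(body, dtype=bool)
    if body.shape != img.grid.shape:
        raise ValueError("body mask is not on the image grid")
    hu = img.voxels
    air = ~body
    lung = body & (hu < thresholds.lung_upper_hu)
    bone = body & (hu > thresholds.bone_lower_hu)
    soft = body & ~lung & ~bone
    masks = TissueMaskSet(grid=img.grid, air=air, lung=lung, soft=soft,
                          bone=bone, body=body)
    return clean_masks(masks, thresholds.min_component_mm3)


def clean_masks(masks: TissueMaskSet, min_component_mm3: float) -> TissueMaskSet:
    """Reassign lung/bone connected components below the size floor to soft."""
    out = masks.copy()
    if min_component_mm3 <= 0:
        return out
    voxel_mm3 = masks.grid.voxel_volume_mm3
    min_voxels = min_component_mm3 / voxel_mm3
    for name in ("lung", "bone"):
        mask = out.class_mask(name)
        labels, n = ndimage.label(mask)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        small = np.zeros(n + 1, dtype=bool)
        small[1:] = sizes[1:] < min_voxels
        drop = small[labels]
        mask &= ~drop
        out.soft |= drop
    out.validate_partition()
    return out


def suppress_fov_edge(masks: TissueMaskSet, fov: np.ndarray,
                      ring_voxels: int = 2) -> TissueMaskSet:
    """Demote lung/bone in the FOV boundary ring to soft tissue.

    Partial-object truncation at the reconstructed-volume edge produces
    spurious class transitions; voxels within ``ring_voxels`` of the FOV
    boundary are kept but treated as soft so their ratios are estimated
    from the robust class.
    """
    fov = np.asarray(fov, dtype=bool)
    if fov.all() or ring_voxels <= 0:
        return masks.copy()
    padded = np.pad(fov, ring_voxels, mode="edge")
    interior = ndimage.binary_erosion(padded, iterations=ring_voxels)
    interior = interior[ring_voxels:-ring_voxels,
                        ring_voxels:-ring_voxels,
                        ring_voxels:-ring_voxels]
    ring = fov & ~interior
    out = masks.copy()
    demote = (out.lung | out.bone) & ring
    out.lung &= ~demote
    out.bone &= ~demote
    out.soft |= demote
    out.fov = fov
    out.validate_partition()
    return out


def segment_image(img: VolumetricImage,
                  thresholds: SegmentationThresholds | None = None,
                  fov: np.ndarray | None = None,
                  edge_ring_voxels: int = 2) -> TissueMaskSet:
    """Full segmentation of one image: body mask, class split, cleanup.

    When a ``fov`` mask is given (CBCT with truncated support) the body is
    confined to it and lung/bone are suppressed in the FOV edge ring.
    """
    thresholds = thresholds or SegmentationThresholds()
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        hu = np.where(fov, img.voxels, -1000.0)
        img = img.copy_with(hu)
    body = compute_body_mask(img, thresholds.body_threshold_hu)
    if fov is not None:
        body &= fov
    masks = segment_tissues(img, thresholds, body)
    if fov is not None:
        masks = suppress_fov_edge(masks, fov, edge_ring_voxels)
    return masks
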