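"""Digital thorax/breast phantom and synthetic CBCT degradation.

The phantom is a constructive-geometry stand-in for an anthropomorphic
thorax: an elliptical-cylinder trunk of soft tissue with two lung
ellipsoids, a spinal column, rib spheres, and a hemi-ellipsoidal breast
protrusion on one side. Each voxel belongs to exactly one of the four
tissue classes (air, lung, soft, bone) at a known mean HU, with seeded
Gaussian intra-class texture on the tissue classes. Exterior air carries
no texture and sits exactly at -1000 HU, the physical floor of the scale.

The degradation turns the clean CT into a synthetic CBCT exhibiting the
artifacts the correction targets, applied on the attenuation-proportional
scale mu = (HU + 1000) / 1000:

* cupping — a smooth multiplicative radial field, darker at the core and
  recovering toward the rim, the signature of unmodelled scatter;
* partial-arc shading — a smooth angular modulation standing in for the
  quality loss of a 200-degree (rather than full-circle) acquisition;
* per-class HU bias — constant offsets per tissue class, emulating the
  object-dependent HU shift of CBCT;
* voxel noise — additive Gaussian HU noise;
* FOV truncation — voxels outside a cylindrical field of view are cut to
  the -1000 HU padding value and excluded from the FOV mask.

The realized multiplicative bias field (everything except noise and
truncation, expressed as a single per-voxel factor on the mu scale) is
returned as ground truth so tests can score correction quality against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import CLASS_NAMES, TissueMaskSet
from .volume_io import ImageGrid, IntensityUnit, RigidTransform, VolumetricImage, resample_to_grid

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "DegradationResult",
    "StandardFixture",
    "default_grid",
    "generate_phantom_ct",
    "degrade_to_cbct",
    "standard_fixture",
]


def default_grid() -> ImageGrid:
    """128 x 128 x 64 voxels at 2.5 mm isotropic, centered on the origin."""
    shape = (128, 128, 64)
    spacing = (2.5, 2.5, 2.5)
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return ImageGrid(shape=shape, spacing=spacing, origin=origin)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the digital thorax phantom.

    World axes are LPS: +x patient-left, +y posterior, +z superior, so the
    breast protrusion (``breast_laterality='left'``) sits at +x / -y. The
    trunk ellipsoid is deliberately longer than the grid along z — a thorax
    scan is a slab through the torso — so only its in-plane fit is checked.
    """

    grid: ImageGrid = field(default_factory=default_grid)
    body_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_semiaxes_mm: tuple[float, float, float] = (140.0, 95.0, 400.0)
    lung_centers_mm: tuple[tuple[float, float, float], ...] = (
        (-55.0, 10.0, 0.0), (55.0, 10.0, 0.0))
    lung_semiaxes_mm: tuple[float, float, float] = (38.0, 55.0, 62.0)
    spine_center_xy_mm: tuple[float, float] = (0.0, 70.0)
    spine_radius_mm: float = 14.0
    rib_radius_mm: float = 6.0
    rib_ring_scale: float = 0.88
    rib_angles_deg: tuple[float, ...] = (30.0, 70.0, 110.0, 150.0, 210.0, 330.0)
    rib_z_levels_mm: tuple[float, ...] = (-50.0, -25.0, 0.0, 25.0, 50.0)
    breast_laterality: str = "left"
    breast_center_mm: tuple[float, float, float] = (70.0, -70.0, 0.0)
    breast_semiaxes_mm: tuple[float, float, float] = (50.0, 45.0, 50.0)
    class_mean_hu: tuple[float, float, float, float] = (-1000.0, -750.0, 40.0, 700.0)
    texture_sd_hu: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.breast_laterality not in ("left", "right"):
            raise ValueError("breast_laterality must be 'left' or 'right'")
        means = dict(zip(CLASS_NAMES, self.class_mean_hu))
        if not (means["air"] < means["lung"] < means["soft"] < means["bone"]):
            raise ValueError("class HU means must be ordered air < lung < soft < bone")
        if self.texture_sd_hu < 0:
            raise ValueError("texture_sd_hu must be >= 0")

    @property
    def class_means(self) -> dict[str, float]:
        return dict(zip(CLASS_NAMES, self.class_mean_hu))


def _ellipsoid(coords: np.ndarray, center, semiaxes) -> np.ndarray:
    d = (coords - np.asarray(center, dtype=float)) / np.asarray(semiaxes, dtype=float)
    return np.sum(d * d, axis=-1) <= 1.0


def _check_inside_grid(grid: ImageGrid, center, semiaxes, what: str,
                       axes=(0, 1, 2)) -> None:
    lo = np.asarray(grid.origin) - np.asarray(grid.spacing) / 2.0
    hi = lo + np.asarray(grid.extent_mm)
    c, s = np.asarray(center, dtype=float), np.asarray(semiaxes, dtype=float)
    for ax in axes:
        if c[ax] - s[ax] < lo[ax] or c[ax] + s[ax] > hi[ax]:
            raise ValueError(f"{what} extends outside the grid along axis {ax}")


def generate_phantom_ct(spec: PhantomSpec | None = None
                        ) -> tuple[VolumetricImage, TissueMaskSet]:
    """Build the clean phantom CT and its exact constructive class masks."""
    spec = spec or PhantomSpec()
    grid = spec.grid
    coords = grid.world_coordinates()
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]

    # body trunk: validated in-plane only (it runs through the z slab)
    _check_inside_grid(grid, spec.body_center_mm, spec.body_semiaxes_mm,
                       "body", axes=(0, 1))
    body = _ellipsoid(coords, spec.body_center_mm, spec.body_semiaxes_mm)

    bc = np.asarray(spec.breast_center_mm, dtype=float)
    if spec.breast_laterality == "right":
        bc = bc * np.array([-1.0, 1.0, 1.0])
    _check_inside_grid(grid, bc, spec.breast_semiaxes_mm, "breast protrusion")
    # hemi-ellipsoid: anterior (-y) half plus whatever overlaps the trunk
    breast = _ellipsoid(coords, bc, spec.breast_semiaxes_mm) & (y <= bc[1] + spec.breast_semiaxes_mm[1])
    body_total = body | breast

    lung = np.zeros(grid.shape, dtype=bool)
    for center in spec.lung_centers_mm:
        _check_inside_grid(grid, center, spec.lung_semiaxes_mm, "lung")
        lung |= _ellipsoid(coords, center, spec.lung_semiaxes_mm)
    lung &= body

    bone = np.zeros(grid.shape, dtype=bool)
    sx, sy = spec.spine_center_xy_mm
    bone |= ((x - sx) ** 2 + (y - sy) ** 2 <= spec.spine_radius_mm ** 2)
    ax, ay = (spec.rib_ring_scale * s for s in spec.body_semiaxes_mm[:2])
    for zc in spec.rib_z_levels_mm:
        for ang in spec.rib_angles_deg:
            a = math.radians(ang)
            center = (spec.body_center_mm[0] + ax * math.cos(a),
                      spec.body_center_mm[1] + ay * math.sin(a),
                      zc)
            _check_inside_grid(grid, center, (spec.rib_radius_mm,) * 3, "rib")
            bone |= _ellipsoid(coords, center, (spec.rib_radius_mm,) * 3)
    bone &= body_total
    lung &= ~bone  # bone (ribs touching lung boundary) wins

    soft = body_total & ~lung & ~bone
    air = ~body_total
    masks = TissueMaskSet(grid=grid, air=air, lung=lung, soft=soft, bone=bone,
                          body=body_total)

    means = spec.class_means
    hu = np.full(grid.shape, means["air"], dtype=np.float64)
    rng = np.random.default_rng(spec.seed)
    texture = rng.normal(0.0, spec.texture_sd_hu, size=grid.shape)
    for name in ("lung", "soft", "bone"):
        m = masks.class_mask(name)
        hu[m] = means[name] + texture[m]
    ct = VolumetricImage(grid=grid, voxels=hu, unit=IntensityUnit.HU)
    return ct, masks


@dataclass(frozen=True)
class DegradationSpec:
    """Parameters of the synthetic CBCT degradation.

    ``cupping_amplitude`` is the fractional attenuation deficit at the FOV
    axis, recovering over ``cupping_length_mm``; ``arc_gap_center_deg`` is
    the mid-angle of the unscanned sector of the partial arc, measured in
    the axial plane from +x toward +y; per-class shifts are HU offsets in
    the order (air, lung, soft, bone). ``fov_radius_mm`` = 100 mm covers
    roughly 70 % of the default 140 mm body half-width.
    """

    cupping_amplitude: float = 0.15
    cupping_length_mm: float = 80.0
    per_class_hu_shift: tuple[float, float, float, float] = (0.0, -30.0, -40.0, -60.0)
    arc_shading_amplitude: float = 0.05
    arc_span_deg: float = 200.0
    arc_gap_center_deg: float = 170.0
    noise_sd_hu: float = 15.0
    fov_radius_mm: float = 100.0
    fov_center_xy_mm: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cupping_amplitude <= 0.5):
            raise ValueError("cupping_amplitude must be in [0, 0.5]")
        if not (0.0 <= self.arc_shading_amplitude <= 0.5):
            raise ValueError("arc_shading_amplitude must be in [0, 0.5]")
        if self.fov_radius_mm <= 0:
            raise ValueError("fov_radius_mm must be > 0")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")

    @property
    def class_shifts(self) -> dict[str, float]:
        return dict(zip(CLASS_NAMES, self.per_class_hu_shift))


@dataclass
class DegradationResult:
    """Synthetic CBCT plus the ground truth needed to score a correction."""

    cbct: VolumetricImage
    fov: np.ndarray
    bias_field: VolumetricImage  # realized multiplicative factor on the mu scale
    spec: DegradationSpec


def _mu(hu: np.ndarray) -> np.ndarray:
    return np.clip((hu + 1000.0) / 1000.0, 0.0, None)


def degrade_to_cbct(ct: VolumetricImage, truth_masks: TissueMaskSet,
                    spec: DegradationSpec | None = None) -> DegradationResult:
    """Degrade a clean CT into a synthetic CBCT with known ground truth.

    The returned ``bias_field`` is the exact per-voxel multiplicative
    factor on the mu scale combining cupping, arc shading, and the
    per-class shift, so that ``mu_clean * bias`` reproduces the noise-free
    degraded image inside the FOV.
    """
    spec = spec or DegradationSpec()
    grid = ct.grid
    coords = grid.world_coordinates()
    cx, cy = spec.fov_center_xy_mm
    dx, dy = coords[..., 0] - cx, coords[..., 1] - cy
    r = np.hypot(dx, dy)

    cupping = 1.0 - spec.cupping_amplitude * np.exp(-(r / spec.cupping_length_mm) ** 2)

    theta = np.degrees(np.arctan2(dy, dx))
    dtheta = np.abs((theta - spec.arc_gap_center_deg + 180.0) % 360.0 - 180.0)
    half_gap = (360.0 - spec.arc_span_deg) / 2.0
    window = np.where(dtheta < half_gap,
                      0.5 * (1.0 + np.cos(np.pi * dtheta / max(half_gap, 1e-9))),
                      0.0)
    arc = 1.0 - spec.arc_shading_amplitude * window

    mu_clean = _mu(ct.voxels)
    mu_deg = mu_clean * cupping * arc
    hu_deg = mu_deg * 1000.0 - 1000.0
    for name, shift in spec.class_shifts.items():
        if shift:
            hu_deg[truth_masks.class_mask(name)] += shift
    mu_nonoise = _mu(hu_deg)

    # realized multiplicative bias: exact, including the additive class shift
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = np.where(mu_clean > 1e-12, mu_nonoise / np.maximum(mu_clean, 1e-12), 1.0)

    rng = np.random.default_rng(spec.seed)
    hu_out = mu_nonoise * 1000.0 - 1000.0
    if spec.noise_sd_hu > 0:
        hu_out = hu_out + rng.normal(0.0, spec.noise_sd_hu, size=grid.shape)

    fov = r <= spec.fov_radius_mm
    hu_out = np.where(fov, hu_out, -1000.0)
    cbct = VolumetricImage(grid=grid, voxels=hu_out, unit=IntensityUnit.HU)
    bias_img = VolumetricImage(grid=grid, voxels=bias, unit=IntensityUnit.RATIO)
    return DegradationResult(cbct=cbct, fov=fov, bias_field=bias_img, spec=spec)


@dataclass
class StandardFixture:
    """Default phantom + degradation + a fixed rigid offset, for tests and docs."""

    ct: VolumetricImage
    cbct: VolumetricImage              # degraded, in its own (offset) frame
    truth_masks: TissueMaskSet
    truth_transform: RigidTransform    # maps CBCT world coords into CT world coords
    truth_bias: VolumetricImage        # on the CT grid
    cbct_aligned: VolumetricImage      # degraded CBCT already on the CT grid
    fov_aligned: np.ndarray            # FOV mask on the CT grid
    phantom_spec: PhantomSpec
    degradation_spec: DegradationSpec


def standard_fixture(seed: int = 0,
                     phantom_spec: PhantomSpec | None = None,
                     degradation_spec: DegradationSpec | None = None,
                     offset: RigidTransform | None = None) -> StandardFixture:
    """Package the default study conditions behind a single seed.

    The CBCT is the degraded phantom observed in a frame offset by
    (3, -2, 1) mm and 2 degrees about the axial (z) axis, so the fixture
    exercises registration, resampling, and correction together. The
    returned ``truth_transform`` maps CBCT coordinates back into CT
    coordinates; ``cbct_aligned`` skips the offset for tests that focus on
    the correction alone.
    """
    pspec = phantom_spec or PhantomSpec(seed=seed)
    dspec = degradation_spec or DegradationSpec(seed=seed + 1)
    ct, truth_masks = generate_phantom_ct(pspec)
    deg = degrade_to_cbct(ct, truth_masks, dspec)

    if offset is None:
        center = tuple(ct.grid.center_mm())
        offset = RigidTransform(rotation_deg=(0.0, 0.0, 2.0),
                                translation_mm=(3.0, -2.0, 1.0),
                                center_mm=center)
    # construct the CBCT in its own frame: resampling it back through the
    # truth transform recovers the aligned degraded image
    cbct_shifted, _ = resample_to_grid(deg.cbct, ct.grid, offset.inverse(),
                                       interpolation="linear")
    return StandardFixture(
        ct=ct,
        cbct=cbct_shifted,
        truth_masks=truth_masks,
        truth_transform=offset,
        truth_bias=deg.bias_field,
        cbct_aligned=deg.cbct,
        fov_aligned=deg.fov,
        phantom_spec=pspec,
        degradation_spec=dspec,
    )
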