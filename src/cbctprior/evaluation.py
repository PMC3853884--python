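"""Correction-quality metrics: histograms, HU errors, WEPL surrogates.

Three complementary views of how close a (corrected) CBCT is to the
planning CT:

* **intensity histograms** — the classic visual check that the corrected
  image's HU distribution moves toward the CT's, made quantitative with
  L1, chi-square, and earth-mover distances on bin frequencies;
* **HU error metrics** — MAE/RMSE over body-and-FOV, plus per-class
  signed mean errors against ground-truth class masks;
* **water-equivalent path length (WEPL)** — the density line integral a
  dose engine effectively consumes; per-ray WEPL discrepancies are the
  image-level driver of dose differences, replacing out-of-scope TPS
  dosimetry with a desk-scale surrogate.

Histograms are compared on frequencies, not counts, since the two images
may be evaluated over masks of different size; the comparison is about
distribution shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import CLASS_NAMES, TissueMaskSet
from .volume_io import CbctPriorError, IntensityUnit, VolumetricImage

__all__ = [
    "IntensityHistogram",
    "HuErrorReport",
    "DensityCalibration",
    "WeplReport",
    "default_hu_edges",
    "intensity_histogram",
    "histogram_distance",
    "hu_error_metrics",
    "hu_to_density",
    "wepl_along_ray",
    "wepl_discrepancy_map",
]


class ConfigurationError(CbctPriorError):
    """Invalid evaluation configuration (e.g. non-monotone calibration)."""


def default_hu_edges() -> np.ndarray:
    """-1100 to +1500 HU in 10 HU bins."""
    return np.arange(-1100.0, 1500.0 + 10.0, 10.0)


@dataclass
class IntensityHistogram:
    """Binned HU counts over a masked region; end bins are open-ended."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mask_description: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


def intensity_histogram(img: VolumetricImage, mask: np.ndarray,
                        edges: np.ndarray | None = None,
                        description: str = "") -> IntensityHistogram:
    """Histogram of masked voxel intensities.

    Values beyond the edge range accumulate in the first/last bin, so the
    counts always sum to the number of masked voxels.
    """
    edges = default_hu_edges() if edges is None else np.asarray(edges, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to histogram")
    values = img.voxels[mask]
    counts, _ = np.histogram(values, bins=edges)
    counts[0] += int(np.sum(values < edges[0]))
    counts[-1] += int(np.sum(values >= edges[-1]))
    return IntensityHistogram(bin_edges=edges, counts=counts,
                              mask_description=description)


def histogram_distance(a: IntensityHistogram, b: IntensityHistogram,
                       metric: str = "l1") -> float:
    """Distance between two histograms' frequency distributions.

    ``l1``: sum of absolute frequency differences. ``chi2``: half the
    chi-square statistic on frequencies. ``emd``: 1-D earth-mover
    distance (in intensity units, i.e. HU for HU histograms).
    """
    if a.bin_edges.shape != b.bin_edges.shape or not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError("histograms have mismatched bin edges")
    p, q = a.frequencies, b.frequencies
    if metric == "l1":
        return float(np.sum(np.abs(p - q)))
    if metric == "chi2":
        denom = p + q
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(denom > 0, (p - q) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
        return float(0.5 * np.sum(terms))
    if metric == "emd":
        widths = np.diff(a.bin_edges)
        cdf_diff = np.cumsum(p - q)
        return float(np.sum(np.abs(cdf_diff) * widths))
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class HuErrorReport:
    """MAE/RMSE plus per-class signed mean errors, in HU."""

    mae_hu: float
    rmse_hu: float
    class_mean_error_hu: dict[str, float]
    n_voxels: int
    mask_description: str = ""

    def __post_init__(self) -> None:
        assert self.rmse_hu >= self.mae_hu >= 0.0 or np.isnan(self.rmse_hu)


def hu_error_metrics(test: VolumetricImage, reference: VolumetricImage,
                     masks: TissueMaskSet,
                     description: str = "body & fov") -> HuErrorReport:
    """HU error of ``test`` against ``reference`` over body-and-FOV.

    Per-class signed means use the class masks of ``masks`` (typically
    phantom ground truth) intersected with the evaluation region.
    """
    if test.grid.shape != reference.grid.shape:
        raise ValueError("images must share a grid")
    region = masks.body & masks.fov
    if not region.any():
        raise ValueError("empty evaluation region (body & fov)")
    diff = test.voxels - reference.voxels
    d = diff[region]
    per_class: dict[str, float] = {}
    for name in CLASS_NAMES:
        cmask = masks.class_mask(name) & region
        per_class[name] = float(diff[cmask].mean()) if cmask.any() else float("nan")
    return HuErrorReport(
        mae_hu=float(np.abs(d).mean()),
        rmse_hu=float(np.sqrt(np.mean(d ** 2))),
        class_mean_error_hu=per_class,
        n_voxels=int(region.sum()),
        mask_description=description,
    )


@dataclass(frozen=True)
class DensityCalibration:
    """Piecewise-linear HU -> relative electron density curve.

    A fixed surrogate for a scanner-specific calibration; extrapolation
    beyond the control points is clamped to the end values.
    """

    control_points: tuple[tuple[float, float], ...] = (
        (-1000.0, 0.001), (-750.0, 0.25), (0.0, 1.0),
        (200.0, 1.10), (700.0, 1.43), (1500.0, 1.85),
    )

    def __post_init__(self) -> None:
        hu = np.array([p[0] for p in self.control_points])
        rho = np.array([p[1] for p in self.control_points])
        if not np.all(np.diff(hu) > 0):
            raise ConfigurationError("calibration HU values must be increasing")
        if np.any(np.diff(rho) < 0):
            raise ConfigurationError("calibration density must be non-decreasing")

    def to_density(self, hu: np.ndarray) -> np.ndarray:
        xs = np.array([p[0] for p in self.control_points])
        ys = np.array([p[1] for p in self.control_points])
        return np.interp(hu, xs, ys)  # np.interp clamps outside the range


def hu_to_density(img: VolumetricImage,
                  cal: DensityCalibration | None = None) -> VolumetricImage:
    """Convert an HU image to relative electron density."""
    cal = cal or DensityCalibration()
    if img.unit is not IntensityUnit.HU:
        raise ValueError(f"expected an HU image, got {img.unit}")
    rho = cal.to_density(img.voxels)
    return img.copy_with(rho, unit=IntensityUnit.DENSITY,
                         padding_value=float(cal.to_density(np.array(-1000.0))))


def _ray_exit_t(grid_shape, idx0: np.ndarray, didx: np.ndarray) -> float:
    """Distance (in t units) until the ray leaves the index-space box."""
    lo = np.zeros(3)
    hi = np.asarray(grid_shape, dtype=float) - 1.0
    t_exit = np.inf
    for ax in range(3):
        if abs(didx[ax]) < 1e-12:
            if idx0[ax] < lo[ax] or idx0[ax] > hi[ax]:
                return 0.0
            continue
        t1 = (lo[ax] - idx0[ax]) / didx[ax]
        t2 = (hi[ax] - idx0[ax]) / didx[ax]
        t_exit = min(t_exit, max(t1, t2))
    return max(t_exit, 0.0)


def wepl_along_ray(density: VolumetricImage, entry_point: np.ndarray,
                   direction: np.ndarray, step_mm: float = 1.0) -> float:
    """Water-equivalent path length: trapezoidal density integral (mm).

    The ray starts at ``entry_point`` (world mm, must lie inside the grid)
    and marches along the unit ``direction`` until it exits the volume.
    ``step_mm`` should be at most half the smallest voxel spacing for the
    0.5 % convergence guarantee.
    """
    if density.unit is not IntensityUnit.DENSITY:
        raise ValueError("wepl_along_ray expects a DENSITY image")
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("direction must be a nonzero vector")
    direction = direction / norm
    entry = np.asarray(entry_point, dtype=float)

    grid = density.grid
    idx0 = grid.world_to_index(entry)
    n = np.asarray(grid.shape, dtype=float)
    if np.any(idx0 < 0.0) or np.any(idx0 > n - 1.0):
        raise ValueError(f"entry point {entry} lies outside the grid")
    # direction in continuous-index units per mm of world travel
    didx = grid.world_to_index(entry + direction) - idx0
    t_exit = _ray_exit_t(grid.shape, idx0, didx)
    if t_exit <= 0.0:
        return 0.0
    ts = np.arange(0.0, t_exit + step_mm / 2.0, step_mm)
    ts[-1] = min(ts[-1], t_exit)
    pts = idx0[None, :] + ts[:, None] * didx[None, :]
    samples = ndimage.map_coordinates(density.voxels, pts.T, order=1, mode="nearest")
    return float(np.trapezoid(samples, ts))


@dataclass
class WeplReport:
    """Per-ray WEPL differences for a parallel beam (mm of water)."""

    mean_abs_mm: float
    max_abs_mm: float
    mean_signed_mm: float
    n_rays: int
    differences_mm: np.ndarray = field(repr=False, default=None)  # type: ignore


def wepl_discrepancy_map(test: VolumetricImage, reference: VolumetricImage,
                         body: np.ndarray,
                         cal: DensityCalibration | None = None,
                         direction: np.ndarray = (0.0, 1.0, 0.0),
                         ray_spacing_mm: float = 5.0,
                         step_mm: float = 1.0) -> WeplReport:
    """Per-ray WEPL difference between two HU images.

    A regular grid of parallel rays (default anterior-to-posterior, i.e.
    along +y, mimicking a tangential-beam face) is cast across the volume
    at ``ray_spacing_mm``; only rays traversing the ``body`` mask count.
    """
    cal = cal or DensityCalibration()
    if test.grid.shape != reference.grid.shape:
        raise ValueError("images must share a grid")
    rho_test = hu_to_density(test, cal)
    rho_ref = hu_to_density(reference, cal)
    body = np.asarray(body, dtype=bool)
    body_img = VolumetricImage(grid=test.grid, voxels=body.astype(np.float64),
                               unit=IntensityUnit.DENSITY, padding_value=0.0)

    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    grid = test.grid
    # build the beam face: the two axes least aligned with the direction
    d_index = np.abs(grid.world_to_index(np.asarray(grid.origin) + direction)
                     - grid.world_to_index(np.asarray(grid.origin)))
    main_axis = int(np.argmax(d_index))
    face_axes = [ax for ax in range(3) if ax != main_axis]

    extents = grid.extent_mm
    diffs = []
    for u in np.arange(0.0, extents[face_axes[0]] - 1e-9, ray_spacing_mm):
        for v in np.arange(0.0, extents[face_axes[1]] - 1e-9, ray_spacing_mm):
            idx = np.zeros(3)
            idx[face_axes[0]] = u / grid.spacing[face_axes[0]]
            idx[face_axes[1]] = v / grid.spacing[face_axes[1]]
            idx[main_axis] = 0.0
            nmax = np.asarray(grid.shape) - 1
            if np.any(idx > nmax):
                continue
            entry = grid.index_to_world(idx)
            body_path = wepl_along_ray(body_img, entry, direction, step_mm)
            if body_path <= 0.0:
                continue
            w_test = wepl_along_ray(rho_test, entry, direction, step_mm)
            w_ref = wepl_along_ray(rho_ref, entry, direction, step_mm)
            diffs.append(w_test - w_ref)
    if not diffs:
        raise ValueError("no ray intersects the body mask")
    d = np.asarray(diffs)
    return WeplReport(
        mean_abs_mm=float(np.abs(d).mean()),
        max_abs_mm=float(np.abs(d).max()),
        mean_signed_mm=float(d.mean()),
        n_rays=len(d),
        differences_mm=d,
    )
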