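"""Volumetric images with explicit world geometry, file I/O, and resampling.

Conventions
-----------
* World coordinates are LPS axes in millimetres (the radiotherapy-imaging
  standard); voxel indices are 0-based and ``origin`` is the world position of
  the *center* of voxel (0, 0, 0).
* Voxel arrays are indexed ``[i, j, k]`` along the x/y/z grid axes.
* Rigid transforms use Euler angles in degrees applied in fixed Z-Y-X order
  (``R = Rz @ Ry @ Rx``), mapping a point as ``x' = R (x - c) + c + t``.
* Out-of-support fill is -1000 HU (air) for HU images and 1.0 for ratio
  images: physically neutral values.

Files are NIfTI (``.nii``/``.nii.gz``) or MetaImage (``.mha``/``.mhd``); a
small JSON sidecar (``<path>.json``) records the intensity unit and padding
value, which neither format carries natively.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "IntensityUnit",
    "ImageGrid",
    "VolumetricImage",
    "RigidTransform",
    "FormatError",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "default_padding",
]


class CbctPriorError(Exception):
    """Base class for package errors."""


class FormatError(CbctPriorError):
    """Unreadable, unwritable, or non-3-D image file."""


class IntensityUnit(str, Enum):
    HU = "HU"
    MU_RELATIVE = "MU_RELATIVE"
    RATIO = "RATIO"
    DENSITY = "DENSITY"


def default_padding(unit: IntensityUnit) -> float:
    """Physically neutral out-of-support value for each intensity unit."""
    return {
        IntensityUnit.HU: -1000.0,
        IntensityUnit.MU_RELATIVE: 0.0,
        IntensityUnit.RATIO: 1.0,
        IntensityUnit.DENSITY: 0.0,
    }[unit]


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3-D voxel lattice embedded in world space.

    Parameters
    ----------
    shape : tuple of 3 ints
        Voxel counts along the x, y, z grid axes.
    spacing : tuple of 3 floats
        Millimetres per voxel along each axis; strictly positive.
    origin : tuple of 3 floats
        World coordinates (mm) of the center of voxel (0, 0, 0).
    direction : 3x3 array
        Direction-cosine matrix; column ``j`` is the world-space unit vector
        of grid axis ``j``. Must be orthonormal within 1e-6.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        d = self.direction_matrix
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(
            self, "direction", tuple(float(v) for v in np.asarray(self.direction).ravel())
        )

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid (mm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) @ self.direction_matrix.T + np.asarray(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world points, shape (..., 3), to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) @ self.direction_matrix / np.asarray(self.spacing)

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1)
        return self.index_to_world(idx)

    def center_mm(self) -> np.ndarray:
        """World coordinates of the geometric center of the grid."""
        mid = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.index_to_world(mid)


@dataclass
class VolumetricImage:
    """A scalar voxel volume plus its grid and intensity semantics."""

    grid: ImageGrid
    voxels: np.ndarray
    unit: IntensityUnit = IntensityUnit.HU
    padding_value: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"voxel array shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )
        if self.padding_value is None:
            self.padding_value = default_padding(self.unit)

    def copy_with(self, voxels: np.ndarray, unit: IntensityUnit | None = None,
                  padding_value: float | None = None) -> "VolumetricImage":
        return VolumetricImage(
            grid=self.grid,
            voxels=voxels,
            unit=unit if unit is not None else self.unit,
            padding_value=padding_value,
        )

    def to_sitk(self) -> sitk.Image:
        # SimpleITK arrays are indexed [z, y, x]
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.transpose(2, 1, 0)))
        img.SetSpacing(self.grid.spacing)
        img.SetOrigin(self.grid.origin)
        img.SetDirection(self.grid.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, unit: IntensityUnit = IntensityUnit.HU,
                  padding_value: float | None = None) -> "VolumetricImage":
        if img.GetDimension() != 3:
            raise FormatError(f"expected a 3-D image, got {img.GetDimension()}-D")
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        grid = ImageGrid(
            shape=tuple(img.GetSize()),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=tuple(img.GetDirection()),
        )
        return cls(grid=grid, voxels=arr, unit=unit, padding_value=padding_value)


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def euler_zyx_from_matrix(m: np.ndarray) -> tuple[float, float, float]:
    """Recover (rx, ry, rz) in degrees from ``R = Rz @ Ry @ Rx``."""
    m = np.asarray(m, dtype=float)
    sy = -m[2, 0]
    sy = min(1.0, max(-1.0, sy))
    ry = math.asin(sy)
    if abs(math.cos(ry)) > 1e-8:
        rx = math.atan2(m[2, 1], m[2, 2])
        rz = math.atan2(m[1, 0], m[0, 0])
    else:  # gimbal lock: fold rx into rz
        rx = 0.0
        rz = math.atan2(-m[0, 1], m[1, 1])
    return math.degrees(rx), math.degrees(ry), math.degrees(rz)


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF world-space rigid mapping ``x' = R (x - c) + c + t``.

    ``rotation_deg`` are Euler angles (degrees) about x, y, z applied in
    Z-Y-X order; ``translation_mm`` is ``t``; ``center_mm`` is ``c``.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "translation_mm", "center_mm"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != 3:
                raise ValueError(f"{name} must have 3 components")
            object.__setattr__(self, name, v)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = (math.radians(a) for a in self.rotation_deg)
        return _rot_z(rz) @ _rot_y(ry) @ _rot_x(rx)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform world points of shape (..., 3)."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (p - c) @ self.matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        r = self.matrix
        rx, ry, rz = euler_zyx_from_matrix(r.T)
        t_inv = -r.T @ np.asarray(self.translation_mm)
        return RigidTransform(
            rotation_deg=(rx, ry, rz),
            translation_mm=tuple(t_inv),
            center_mm=self.center_mm,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        a1, a2 = other.matrix, self.matrix
        # affine form x' = A x + p
        p1 = np.asarray(other.center_mm) + np.asarray(other.translation_mm) - a1 @ np.asarray(other.center_mm)
        p2 = np.asarray(self.center_mm) + np.asarray(self.translation_mm) - a2 @ np.asarray(self.center_mm)
        a = a2 @ a1
        p = a2 @ p1 + p2
        rx, ry, rz = euler_zyx_from_matrix(a)
        return RigidTransform(rotation_deg=(rx, ry, rz), translation_mm=tuple(p))

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetComputeZYX(True)
        t.SetCenter(self.center_mm)
        t.SetRotation(*(math.radians(a) for a in self.rotation_deg))
        t.SetTranslation(self.translation_mm)
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        m = np.array(t.GetMatrix()).reshape(3, 3)
        rx, ry, rz = euler_zyx_from_matrix(m)
        return cls(
            rotation_deg=(rx, ry, rz),
            translation_mm=tuple(t.GetTranslation()),
            center_mm=tuple(t.GetCenter()),
        )

    # serialization: plain-text key=value record (9 numbers)
    def save(self, path: str | Path) -> None:
        lines = [
            "rotation_deg = " + " ".join(repr(v) for v in self.rotation_deg),
            "translation_mm = " + " ".join(repr(v) for v in self.translation_mm),
            "center_mm = " + " ".join(repr(v) for v in self.center_mm),
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        fields: dict[str, tuple[float, ...]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition("=")
            fields[key.strip()] = tuple(float(v) for v in rest.split())
        try:
            return cls(
                rotation_deg=fields["rotation_deg"],
                translation_mm=fields["translation_mm"],
                center_mm=fields.get("center_mm", (0.0, 0.0, 0.0)),
            )
        except KeyError as exc:
            raise FormatError(f"transform file {path} missing key {exc}") from exc


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_KNOWN_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def read_volume(path: str | Path) -> VolumetricImage:
    """Read a NIfTI or MetaImage volume; raises :class:`FormatError` otherwise."""
    path = Path(path)
    if not str(path).endswith(_KNOWN_SUFFIXES):
        raise FormatError(f"unsupported image format: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # RuntimeError from ITK
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    unit = IntensityUnit.HU
    padding = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        unit = IntensityUnit(meta.get("intensity_unit", "HU"))
        padding = meta.get("padding_value")
    return VolumetricImage.from_sitk(img, unit=unit, padding_value=padding)


def write_volume(img: VolumetricImage, path: str | Path) -> None:
    """Write ``img`` losslessly; a JSON sidecar records unit and padding."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FormatError(f"parent directory does not exist: {path.parent}")
    try:
        sitk.WriteImage(img.to_sitk(), str(path))
    except Exception as exc:
        raise FormatError(f"cannot write image file {path}: {exc}") from exc
    _sidecar_path(path).write_text(
        json.dumps({"intensity_unit": img.unit.value, "padding_value": img.padding_value})
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(
    moving: VolumetricImage,
    reference: ImageGrid,
    transform: RigidTransform | None = None,
    interpolation: str = "linear",
) -> tuple[VolumetricImage, np.ndarray]:
    """Resample ``moving`` onto ``reference`` through a rigid transform.

    ``transform`` maps moving-image world coordinates into reference world
    coordinates (identity when omitted). Output voxel at reference point
    ``x`` samples ``moving`` at ``transform^-1(x)``.

    Returns
    -------
    resampled : VolumetricImage
        On ``reference``; out-of-support voxels hold ``moving.padding_value``.
    support : ndarray of bool
        True where the sampling point fell inside the moving image.
    """
    if any(n <= 0 for n in reference.shape):
        raise ValueError(f"degenerate reference grid {reference.shape}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    transform = transform or RigidTransform.identity()

    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    resampled = sitk.Resample(
        moving.to_sitk(),
        size=reference.shape,
        transform=transform.inverse().to_sitk(),
        interpolator=interp,
        outputOrigin=reference.origin,
        outputSpacing=reference.spacing,
        outputDirection=reference.direction,
        defaultPixelValue=float(moving.padding_value),
        outputPixelType=sitk.sitkFloat64,
    )
    arr = sitk.GetArrayFromImage(resampled).transpose(2, 1, 0)

    # support: where the inverse-mapped point lies fully inside the moving grid
    pts = reference.world_coordinates().reshape(-1, 3)
    idx = moving.grid.world_to_index(transform.inverse().apply(pts))
    n = np.asarray(moving.grid.shape, dtype=float)
    inside = np.all((idx >= 0.0) & (idx <= n - 1.0), axis=1)
    support = inside.reshape(reference.shape)
    arr = np.where(support, arr, float(moving.padding_value))
    out = VolumetricImage(
        grid=reference, voxels=arr, unit=moving.unit, padding_value=moving.padding_value
    )
    return out, support
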