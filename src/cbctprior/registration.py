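"""Rigid CBCT-to-planning-CT registration.

A clinically supplied transform (as produced by the treatment machine's
own registration) always takes precedence; this module covers the case
where none is available. Mutual information is the default metric because
CBCT HU are systematically biased relative to the planning CT — the bias
is exactly what the downstream correction removes — so intensity-difference
metrics are unreliable.

The optimization is multi-resolution (shrink 4/2/1) with random metric
sampling at a fixed seed, initialized by aligning the centers of mass of
the two body outlines (robust to FOV truncation, which shifts the image
centroid but much less so the overlapping anatomy's).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume_io import CbctPriorError, RigidTransform, VolumetricImage

__all__ = [
    "RegistrationSettings",
    "ConvergenceError",
    "register_rigid",
    "invert_transform",
]


class ConvergenceError(CbctPriorError):
    """Optimizer failed to improve the metric; carries the best transform."""

    def __init__(self, message: str, best_transform: RigidTransform,
                 metric_value: float):
        super().__init__(message)
        self.best_transform = best_transform
        self.metric_value = metric_value


@dataclass(frozen=True)
class RegistrationSettings:
    """Knobs of the rigid registration.

    ``sampling_fraction`` is the fraction of voxels used per metric
    evaluation; ``seed`` fixes the random sample so runs are reproducible.
    ``translation_only`` restricts to 3 DOF.
    """

    metric: str = "mutual_information"
    pyramid_levels: int = 3
    max_iterations_per_level: int = 100
    sampling_fraction: float = 0.1
    seed: int = 0
    translation_only: bool = False
    histogram_bins: int = 50
    body_threshold_hu: float = -500.0

    def __post_init__(self) -> None:
        if self.metric not in ("mutual_information", "mean_squared_error"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.max_iterations_per_level < 1:
            raise ValueError("max_iterations_per_level must be >= 1")


def _body_center_of_mass(img: VolumetricImage, threshold_hu: float) -> np.ndarray:
    mask = img.voxels > threshold_hu
    if not mask.any():
        raise CbctPriorError("no voxels above the body threshold; cannot initialize")
    com_index = np.asarray(ndimage.center_of_mass(mask))
    return img.grid.index_to_world(com_index)


def _build_method(settings: RegistrationSettings) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    if settings.metric == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(
            numberOfHistogramBins=settings.histogram_bins)
    else:
        reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(settings.sampling_fraction, settings.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=settings.max_iterations_per_level,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    levels = settings.pyramid_levels
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    sigmas = [max(s / 2.0, 0.0) for s in shrink]
    sigmas[-1] = 0.0
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    return reg


def register_rigid(fixed: VolumetricImage, moving: VolumetricImage,
                   settings: RegistrationSettings | None = None
                   ) -> tuple[RigidTransform, float]:
    """Estimate the rigid transform mapping ``moving`` onto ``fixed``.

    Returns the transform taking moving-image (CBCT) world coordinates
    into fixed-image (planning CT) world coordinates, plus the final
    metric value (lower is better for both supported metrics).

    Raises :class:`ConvergenceError` (carrying the best-so-far transform)
    if the optimized metric is worse than at the initialization.
    """
    settings = settings or RegistrationSettings()
    # ITK metric evaluation is order-dependent under multithreading; a
    # single work unit makes identical seeds give identical transforms
    n_threads = sitk.ProcessObject.GetGlobalDefaultNumberOfThreads()
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    try:
        return _register(fixed, moving, settings)
    finally:
        sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(n_threads)


def _register(fixed: VolumetricImage, moving: VolumetricImage,
              settings: RegistrationSettings) -> tuple[RigidTransform, float]:
    f_img = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat32)
    m_img = sitk.Cast(moving.to_sitk(), sitk.sitkFloat32)

    com_fixed = _body_center_of_mass(fixed, settings.body_threshold_hu)
    com_moving = _body_center_of_mass(moving, settings.body_threshold_hu)
    # the sitk transform maps fixed-space points into moving space
    init_translation = tuple(com_moving - com_fixed)
    if settings.translation_only:
        initial: sitk.Transform = sitk.TranslationTransform(3, init_translation)
    else:
        euler = sitk.Euler3DTransform()
        euler.SetComputeZYX(True)
        euler.SetCenter(tuple(com_fixed))
        euler.SetTranslation(init_translation)
        initial = euler

    reg = _build_method(settings)
    reg.SetInitialTransform(initial, inPlace=False)

    eval_method = _build_method(settings)
    eval_method.SetInitialTransform(initial, inPlace=False)
    initial_metric = eval_method.MetricEvaluate(f_img, m_img)

    final = reg.Execute(f_img, m_img)
    final_metric = float(reg.GetMetricValue())

    inner = final.Downcast()
    if inner.GetName() == "CompositeTransform":  # Execute wraps the result
        inner = inner.GetNthTransform(0).Downcast()
    if settings.translation_only:
        t = sitk.TranslationTransform(inner)
        fixed_to_moving = RigidTransform(translation_mm=tuple(t.GetOffset()))
    else:
        fixed_to_moving = RigidTransform.from_sitk(sitk.Euler3DTransform(inner))
    result = fixed_to_moving.inverse()  # ours maps moving -> fixed

    if final_metric > initial_metric:
        raise ConvergenceError(
            f"registration diverged: metric {final_metric:.6g} worse than "
            f"initial {initial_metric:.6g}",
            best_transform=result,
            metric_value=final_metric,
        )
    return result, final_metric


def invert_transform(t: RigidTransform) -> RigidTransform:
    """Group inverse; composing with the input yields identity."""
    return t.inverse()
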