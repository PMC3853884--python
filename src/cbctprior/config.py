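"""Run configuration, manifests, and the chained pipeline.

A :class:`RunConfig` bundles every tunable of the simulate / register /
correct / evaluate stages. Configs load from TOML with strict key
checking — an unknown key is an error, not a silent no-op — and the
effective configuration (defaults plus overrides) is serialized into a
JSON manifest next to every output so any stage can be re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .correction import FilterSpec, correct_cbct
from .evaluation import histogram_distance, hu_error_metrics, intensity_histogram, wepl_discrepancy_map
from .phantom import DegradationSpec, PhantomSpec, standard_fixture
from .registration import RegistrationSettings, register_rigid
from .segmentation import SegmentationThresholds
from .volume_io import (
    CbctPriorError,
    RigidTransform,
    VolumetricImage,
    resample_to_grid,
    write_volume,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "config_to_dict",
    "write_manifest",
    "run_pipeline",
]

log = logging.getLogger("cbctprior")


class ConfigError(CbctPriorError):
    """Invalid or unknown configuration key/value."""


@dataclass(frozen=True)
class RunConfig:
    """Effective parameters of a full pipeline run."""

    seed: int = 0
    log_level: str = "INFO"
    thresholds: SegmentationThresholds = field(default_factory=SegmentationThresholds)
    filter: FilterSpec = field(default_factory=FilterSpec)
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    degradation: DegradationSpec = field(default_factory=DegradationSpec)


def _coerce(value: Any, target_type: Any) -> Any:
    if isinstance(value, list):
        return tuple(_coerce(v, None) for v in value)
    return value


def _dataclass_from_dict(cls: type, data: dict[str, Any], context: str) -> Any:
    known = {f.name: f for f in fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown configuration key {context}{key!r}")
        f = known[key]
        default = f.default if f.default is not dataclasses.MISSING else (
            f.default_factory() if f.default_factory is not dataclasses.MISSING else None)
        if is_dataclass(default) and isinstance(value, dict):
            kwargs[key] = _dataclass_from_dict(type(default), value, f"{context}{key}.")
        else:
            kwargs[key] = _coerce(value, f.type)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration under {context or 'top level'}: {exc}") from exc


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load a TOML config file, then apply flat override dicts on top."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        section = data
        *parents, leaf = key.split(".")
        for p in parents:
            section = section.setdefault(p, {})
        section[leaf] = value
    return _dataclass_from_dict(RunConfig, data, "")


def config_to_dict(obj: Any) -> Any:
    """Recursively turn dataclasses/arrays into JSON-serializable values."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: config_to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [config_to_dict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, stage: str, config: Any,
                   inputs: dict[str, str | Path] | None = None,
                   outputs: list[str] | None = None,
                   extra: dict[str, Any] | None = None) -> Path:
    """Write ``<out_dir>/<stage>_manifest.json`` describing a stage run."""
    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "tool": "cbctprior",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "effective_config": config_to_dict(config),
        "inputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                   for name, p in (inputs or {}).items()},
        "outputs": outputs or [],
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 use_truth_transform: bool = False) -> dict[str, Any]:
    """Chained simulate -> register -> correct -> evaluate on the phantom.

    Writes all stage outputs and manifests under ``out_dir`` and returns
    the evaluation report as a dict. With ``use_truth_transform`` the
    simulated ground-truth transform bypasses registration, mirroring a
    clinically supplied alignment.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    t0 = time.perf_counter()
    fx = standard_fixture(config.seed, phantom_spec=config.phantom,
                          degradation_spec=config.degradation)
    write_volume(fx.ct, out_dir / "ct.nii.gz")
    write_volume(fx.cbct, out_dir / "cbct.nii.gz")
    write_volume(fx.truth_bias, out_dir / "bias_field.nii.gz")
    fx.truth_transform.save(out_dir / "truth_transform.txt")
    labels = VolumetricImage(grid=fx.ct.grid,
                             voxels=fx.truth_masks.labelmap().astype(np.float64))
    write_volume(labels, out_dir / "truth_labels.nii.gz")
    log.info("simulate: %.1f s", time.perf_counter() - t0)

    t0 = time.perf_counter()
    if use_truth_transform:
        transform = fx.truth_transform
        metric = float("nan")
    else:
        transform, metric = register_rigid(fx.ct, fx.cbct, config.registration)
    transform.save(out_dir / "transform.txt")
    log.info("register: %.1f s", time.perf_counter() - t0)

    t0 = time.perf_counter()
    result = correct_cbct(fx.ct, fx.cbct, transform,
                          thresholds=config.thresholds, spec=config.filter)
    write_volume(result.corrected, out_dir / "corrected.nii.gz")
    for name, ratio in result.ratio_fields.items():
        write_volume(ratio, out_dir / f"ratio_{name}.nii.gz")
    log.info("correct: %.1f s", time.perf_counter() - t0)

    t0 = time.perf_counter()
    # evaluate against the CT over the corrected image's own FOV/body
    masks_eval = fx.truth_masks.copy()
    masks_eval.fov = result.fov
    cbct_on_ct, _ = resample_to_grid(fx.cbct, fx.ct.grid, transform, "linear")
    err_orig = hu_error_metrics(cbct_on_ct, fx.ct, masks_eval, "original CBCT")
    err_corr = hu_error_metrics(result.corrected, fx.ct, masks_eval, "corrected CBCT")
    region = masks_eval.body & masks_eval.fov
    hist_ct = intensity_histogram(fx.ct, region, description="CT")
    hist_orig = intensity_histogram(cbct_on_ct, region, description="original CBCT")
    hist_corr = intensity_histogram(result.corrected, region, description="corrected CBCT")
    wepl_orig = wepl_discrepancy_map(cbct_on_ct, fx.ct, fx.truth_masks.body)
    wepl_corr = wepl_discrepancy_map(result.corrected, fx.ct, fx.truth_masks.body)

    report = {
        "registration_metric": metric,
        "transform": config_to_dict(transform),
        "mae_original_hu": err_orig.mae_hu,
        "mae_corrected_hu": err_corr.mae_hu,
        "mae_reduction_percent": 100.0 * (1.0 - err_corr.mae_hu / err_orig.mae_hu),
        "rmse_original_hu": err_orig.rmse_hu,
        "rmse_corrected_hu": err_corr.rmse_hu,
        "histogram_distance": {
            m: {"original": histogram_distance(hist_orig, hist_ct, m),
                "corrected": histogram_distance(hist_corr, hist_ct, m)}
            for m in ("l1", "chi2", "emd")
        },
        "wepl_mean_abs_original_mm": wepl_orig.mean_abs_mm,
        "wepl_mean_abs_corrected_mm": wepl_corr.mean_abs_mm,
    }
    (out_dir / "evaluation.json").write_text(json.dumps(report, indent=2))
    log.info("evaluate: %.1f s", time.perf_counter() - t0)

    write_manifest(out_dir, "run", config,
                   outputs=sorted(p.name for p in out_dir.iterdir()),
                   extra={"seed": config.seed})
    return report
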