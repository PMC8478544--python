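"""End-to-end orchestration of the five-step workflow.

Steps: (1) sparse manual contours → dense ROI; (2) automatic wall/lumen
segmentation; (3) optional manual lumen corrections (voxel patches read
from mask files); (4) automatic plaque/lesion segmentation; (5)
quantification.  Every stage reads and writes the declared domain types,
so stages are independently scriptable; the run manifest records all
parameters and input checksums for reproducibility.  The pipeline has no
stochastic step: identical inputs produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import volume_io
from .plaque_seg import PlaqueResult, label_volume, segment_plaques
from .quantify import QuantReport, build_report
from .roi_tools import interpolate_roi
from .volume_io import write_mask
from .wall_lumen_seg import MaskEdit, SegParams, WallLumenResult, segment_wall_lumen

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("aortamorph")


@dataclass
class RunConfig:
    volume_path: str
    contours_path: str
    output_dir: str
    units_scale: float = 1.0
    voxel_size_override: float | None = None
    lumen_add_path: str | None = None
    lumen_remove_path: str | None = None
    params: SegParams = field(default_factory=SegParams)
    save_intermediates: bool = False
    export_meshes: bool = True
    log_level: str = "INFO"


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file; seg_params keys override defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    params = SegParams(**raw.pop("seg_params", {}))
    return RunConfig(params=params, **raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_edit(path: str | None) -> np.ndarray | None:
    if path is None:
        return None
    return volume_io.read_mask(path, role="lumen").data


def run_pipeline(config: RunConfig) -> tuple[WallLumenResult, PlaqueResult, QuantReport]:
    """Execute the full workflow and write all outputs to the run directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if not Path(config.contours_path).exists():
        raise volume_io.ConfigurationError(f"contour file not found: {config.contours_path}")
    volume = volume_io.read_volume(
        config.volume_path, config.units_scale, config.voxel_size_override
    )
    contours = volume_io.read_contours(config.contours_path)
    log.info("loaded volume %s in %.2fs", volume.shape, time.perf_counter() - t0)

    t = time.perf_counter()
    roi = interpolate_roi(contours, volume.shape, volume.voxel_size, volume.origin)
    log.info("ROI interpolation: %.2fs", time.perf_counter() - t)

    edits = None
    add = _load_edit(config.lumen_add_path)
    remove = _load_edit(config.lumen_remove_path)
    if add is not None or remove is not None:
        edits = MaskEdit(add=add, remove=remove)

    t = time.perf_counter()
    wall_lumen = segment_wall_lumen(
        volume, roi, config.params, manual_lumen_edits=edits,
        keep_intermediates=config.save_intermediates,
    )
    log.info("wall/lumen segmentation: %.2fs", time.perf_counter() - t)

    t = time.perf_counter()
    plaques = segment_plaques(
        volume, wall_lumen, config.params, keep_intermediates=config.save_intermediates
    )
    log.info("plaque segmentation: %.2fs", time.perf_counter() - t)

    t = time.perf_counter()
    report = build_report(wall_lumen, plaques)
    log.info("quantification: %.2fs", time.perf_counter() - t)

    _write_outputs(config, out, roi, wall_lumen, plaques, report)
    return wall_lumen, plaques, report


def _write_outputs(config, out: Path, roi, wall_lumen, plaques, report) -> None:
    write_mask(roi, out / "roi.nii.gz")
    write_mask(wall_lumen.wall_mask, out / "wall.nii.gz")
    write_mask(wall_lumen.lumen_mask, out / "lumen.nii.gz")
    write_mask(wall_lumen.aorta_mask, out / "aorta.nii.gz")
    write_mask(plaques.plaque_mask, out / "plaque.nii.gz")
    write_mask(plaques.lesion_mask, out / "lesion.nii.gz")
    if config.save_intermediates:
        for name, m in {**wall_lumen.intermediate, **plaques.intermediate}.items():
            write_mask(m, out / f"intermediate_{name}.nii.gz")

    labels = label_volume(wall_lumen, plaques)
    vs = wall_lumen.wall_mask.voxel_size
    volume_io.write_volume(
        volume_io.GrayscaleVolume(labels.astype(float), vs, wall_lumen.wall_mask.origin),
        out / "labels.nii.gz",
    )
    if config.export_meshes:
        for name, mask in (("lumen", wall_lumen.lumen_mask), ("plaque", plaques.plaque_mask)):
            if mask.count():
                volume_io.export_mesh(mask, out / f"{name}.stl")

    report.to_frame().to_csv(out / "report.csv", index=False, float_format="%.9g")
    report.per_slice.to_csv(out / "per_slice.csv", index=False, float_format="%.9g")

    manifest = {
        "inputs": {
            "volume": {"path": str(config.volume_path), "sha256": _sha256(config.volume_path)},
            "contours": {"path": str(config.contours_path), "sha256": _sha256(config.contours_path)},
        },
        "units_scale": config.units_scale,
        "seg_params": dataclasses.asdict(config.params),
        "save_intermediates": config.save_intermediates,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
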