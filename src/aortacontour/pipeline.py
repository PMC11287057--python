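"""End-to-end pipeline orchestration.

Stages: phantom (optional, when no clinical inputs are given) -> ROI crop ->
centerline -> contour initialization -> Poisson reconstruction -> valve
quantification -> evaluation against the ground truth (phantom runs only).
Every stage materializes its artifacts on disk and is logged into a run
manifest with file digests and wall times, so runs are auditable and
reproducible: identical config and seed give bit-identical masks and CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import __version__
from .centerline import Centerline, compute_centerline
from .contours import build_contour_stack
from .evaluate import average_surface_distance, dice
from .imaging import (BinaryMask, ImageVolume, LandmarkSet, crop_roi,
                      read_landmarks, read_volume, write_landmarks, write_volume)
from .phantom import default_spec, generate_phantom
from .poisson import PoissonParams, reconstruct_mask
from .quantify import ValvePlane, annulus_and_lvot_params, diameter_profile

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "export_training_pair"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Section):
    enabled: bool = True
    image_path: str | None = None        # used when enabled is False
    landmarks_path: str | None = None
    valve_plane_path: str | None = None
    shape: int = 128
    spacing: float = 0.65
    noise_sigma: float = 20.0
    edge_softness: float = 0.8


class RoiConfig(_Section):
    side_mm: float = 80.0
    iso_mm: float = 0.65


class CenterlineConfig(_Section):
    scales_mm: list[float] = [6.0, 8.0, 10.0, 12.0]
    hough_range_mm: list[float] = [5.0, 18.0]
    step_mm: float = 1.0


class ContoursConfig(_Section):
    offset_mm: float = 1.0
    size_mm: float = 60.0
    pixel_mm: float = 0.3
    n_rays: int = 36
    n_out: int = 72
    r_max_mm: float = 25.0


class PoissonConfig(_Section):
    screening_weight: float = 4.0
    bbox_scale: float = 1.1
    samples_per_node: float = 1.0
    depth: int = 7
    isovalue_mode: str = "mean_at_samples"


class QuantifyConfig(_Section):
    lvot_offset_mm: float = 3.0
    pixel_mm: float = 0.2
    profile: bool = True


class EvaluateConfig(_Section):
    enabled: bool = True


class PipelineConfig(_Section):
    seed: int = 0
    out_dir: str = "run_output"
    phantom: PhantomConfig = PhantomConfig()
    roi: RoiConfig = RoiConfig()
    centerline: CenterlineConfig = CenterlineConfig()
    contours: ContoursConfig = ContoursConfig()
    poisson: PoissonConfig = PoissonConfig()
    quantify: QuantifyConfig = QuantifyConfig()
    evaluate: EvaluateConfig = EvaluateConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[dict]
    warnings: list[str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)
        return path


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest_stages: list[dict], name: str, outputs: list[Path], t0: float) -> None:
    manifest_stages.append({
        "stage": name,
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "outputs": {p.name: _digest(p) for p in outputs if p.exists()},
    })
    log.info("stage %s complete (%.1fs)", name, manifest_stages[-1]["wall_time_s"])


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, writing artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    warnings: list[str] = []

    # stage 1: input (phantom or user-supplied NIfTI + landmarks)
    t0 = time.perf_counter()
    truth_mask = None
    if config.phantom.enabled:
        spec = default_spec(seed=config.seed, shape=config.phantom.shape,
                            spacing=config.phantom.spacing)
        spec.noise_sigma = config.phantom.noise_sigma
        spec.edge_softness = config.phantom.edge_softness
        ph = generate_phantom(spec)
        image, landmarks = ph.image, ph.landmarks
        truth_mask = ph.truth_mask
        valve_plane = ValvePlane(origin=ph.valve_plane_origin, normal=ph.valve_plane_normal)
        p_img = write_volume(image, out / "image.nii.gz")
        p_msk = write_volume(truth_mask, out / "truth_mask.nii.gz")
        p_lmk = write_landmarks(landmarks, out / "landmarks.json")
        p_vp = valve_plane.to_json(out / "valve_plane.json")
        ph.truth_centerline.to_json(out / "truth_centerline.json")
        _stage(stages, "phantom", [p_img, p_msk, p_lmk, p_vp], t0)
    else:
        if not (config.phantom.image_path and config.phantom.landmarks_path
                and config.phantom.valve_plane_path):
            raise ValueError("phantom disabled: image_path, landmarks_path and "
                             "valve_plane_path are required")
        image = read_volume(config.phantom.image_path)
        landmarks = read_landmarks(config.phantom.landmarks_path)
        valve_plane = ValvePlane.from_json(config.phantom.valve_plane_path)
        _stage(stages, "load_inputs", [], t0)

    # stage 2: ROI crop
    t0 = time.perf_counter()
    roi = crop_roi(image, landmarks, config.roi.side_mm, config.roi.iso_mm)
    p_roi = write_volume(roi, out / "roi.nii.gz")
    roi_truth = None
    if truth_mask is not None:
        roi_truth = crop_roi(truth_mask, landmarks, config.roi.side_mm, config.roi.iso_mm)
        write_volume(roi_truth, out / "roi_truth_mask.nii.gz")
    _stage(stages, "crop", [p_roi], t0)

    # stage 3: centerline
    t0 = time.perf_counter()
    cl = compute_centerline(
        roi, landmarks,
        scales_mm=config.centerline.scales_mm,
        hough_range_mm=tuple(config.centerline.hough_range_mm),
        step_mm=config.centerline.step_mm,
    )
    p_cl = cl.to_json(out / "centerline.json")
    _stage(stages, "centerline", [p_cl], t0)

    # stage 4: contours
    t0 = time.perf_counter()
    stack = build_contour_stack(
        roi, cl,
        offset_mm=config.contours.offset_mm,
        size_mm=config.contours.size_mm,
        pixel_mm=config.contours.pixel_mm,
        n_rays=config.contours.n_rays,
        n_out=config.contours.n_out,
        r_max_mm=config.contours.r_max_mm,
    )
    p_ct = stack.to_json(out / "contours.json")
    _stage(stages, "contours", [p_ct], t0)

    # stage 5: Poisson reconstruction
    t0 = time.perf_counter()
    params = PoissonParams(
        screening_weight=config.poisson.screening_weight,
        bbox_scale=config.poisson.bbox_scale,
        samples_per_node=config.poisson.samples_per_node,
        depth=config.poisson.depth,
        isovalue_mode=config.poisson.isovalue_mode,
    )
    mask, mesh = reconstruct_mask(stack, roi, cl, params, return_mesh=True)
    p_mask = write_volume(mask, out / "mask.nii.gz")
    mesh.export(out / "surface.ply")
    _stage(stages, "reconstruct", [p_mask, out / "surface.ply"], t0)

    # stage 6: quantification
    t0 = time.perf_counter()
    ann, lvot = annulus_and_lvot_params(
        mask, valve_plane, cl,
        lvot_offset_mm=config.quantify.lvot_offset_mm,
        pixel_mm=config.quantify.pixel_mm,
    )
    import pandas as pd

    params_df = pd.DataFrame([
        dict(site="annulus", d_max_mm=ann.d_max, d_min_mm=ann.d_min, area_mm2=ann.area),
        dict(site="lvot", d_max_mm=lvot.d_max, d_min_mm=lvot.d_min, area_mm2=lvot.area),
    ])
    p_params = out / "params.csv"
    params_df.to_csv(p_params, index=False, float_format="%.6f")
    outputs = [p_params]
    if config.quantify.profile:
        prof = diameter_profile(mask, cl, step_mm=1.0)
        p_prof = out / "profile.csv"
        prof.to_csv(p_prof, index=False, float_format="%.6f")
        outputs.append(p_prof)
    _stage(stages, "quantify", outputs, t0)

    # stage 7 (phantom runs): evaluation vs ground truth on the ROI grid
    if config.evaluate.enabled and roi_truth is not None:
        t0 = time.perf_counter()
        from .poisson import clip_mask

        s_lo = float(stack.contours[0].arclength) + 0.5
        s_hi = float(stack.contours[-1].arclength) - 0.5
        truth_clipped = clip_mask(roi_truth, cl, s_lo, s_hi)
        metrics = dict(
            dsc=dice(mask, truth_clipped),
            asd_mm=average_surface_distance(mask, truth_clipped),
        )
        p_metrics = out / "metrics.json"
        with open(p_metrics, "w") as fh:
            json.dump(metrics, fh, indent=1)
        _stage(stages, "evaluate", [p_metrics], t0)

    manifest = RunManifest(
        config=config.model_dump(),
        version=__version__,
        stages=stages,
        warnings=warnings,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def export_training_pair(
    image: ImageVolume,
    mask: BinaryMask,
    out_dir: str | Path,
    case_id: str,
) -> tuple[Path, Path]:
    """Write an image/mask NIfTI pair with identical affines plus a dataset
    manifest consumable by external segmentation-training frameworks."""
    if not image.same_geometry(mask):
        raise ValueError("image and mask must share grid geometry")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p_img = write_volume(image, out / f"{case_id}_image.nii.gz")
    p_msk = write_volume(mask, out / f"{case_id}_mask.nii.gz")
    manifest_path = out / "dataset.json"
    manifest = {"cases": []}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    manifest["cases"] = [c for c in manifest["cases"] if c["case_id"] != case_id]
    manifest["cases"].append({
        "case_id": case_id,
        "image": p_img.name,
        "mask": p_msk.name,
    })
    manifest["n_cases"] = len(manifest["cases"])
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return p_img, p_msk
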