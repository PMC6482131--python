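"""Pipeline orchestration and configuration.

``run_pipeline`` executes the full longitudinal chain:

    read -> (optional z-crop) -> baseline centerline -> baseline surface ->
    fixed mask -> rigid + affine registration -> single resampling ->
    adaptive threshold -> follow-up surface -> landmark measurement ->
    report + dilatation field

Every stage is logged with wall time and its parameters; intermediate
artifacts are written to the output directory, and a stage failure halts
the pipeline with the stage name, the reason and the paths of the completed
intermediates so the user can fall back to manual interaction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from . import measurement, registration, surface
from .centerline import (
    detect_endpoints,
    extract_path,
    fit_lumen_model,
    recenter,
)
from .errors import AortrackError, PipelineError, SchemaError
from .image_model import crop_z, read_volume, write_volume
from .measurement import DiameterReport, build_landmarks, dilatation_field
from .registration import RegistrationConfig

log = logging.getLogger(__name__)


def _strict_dataclass(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class CropConfig:
    z_lo: int | None = None
    z_hi: int | None = None


@dataclass
class CenterlineConfig:
    lumen_seed: list | None = None      # world mm; default: DESC annotation
    start_point: list | None = None     # manual override (aortic root)
    end_point: list | None = None       # manual override (descending end)
    sample_radius: float = 5.0
    ceiling_sigma: float = 3.0
    recenter_passes: int = 3
    recenter_search_radius: float = 20.0

    def __post_init__(self):
        if not (1.0 <= self.ceiling_sigma <= 10.0):
            raise SchemaError("ceiling_sigma must be in [1, 10]")


@dataclass
class SegmentationConfig:
    smoothing_sigma: float = 1.0
    rings_per_cm: float = 2.0
    vertices_per_ring: int = 16
    levels: int = 2
    iterations: int = 200
    step: float = 0.5
    smooth_weight: float = 0.3
    baseline_search_range: float = 10.0
    followup_search_range: float = 6.0
    threshold_window: float = 20.0

    def __post_init__(self):
        if not (0.0 <= self.smooth_weight <= 1.0):
            raise SchemaError("smooth_weight must be in [0, 1]")
        if self.vertices_per_ring < 3 or self.levels < 0:
            raise SchemaError("invalid mesh refinement parameters")


@dataclass
class MeasurementConfig:
    curve_step: float = 2.0

    def __post_init__(self):
        if self.curve_step <= 0:
            raise SchemaError("curve_step must be positive")


@dataclass
class PipelineConfig:
    """Nested parameter blocks for every stage plus the global seed."""

    crop: CropConfig = field(default_factory=CropConfig)
    centerline: CenterlineConfig = field(default_factory=CenterlineConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    seed: int = 0
    save_aligned_volume: bool = False

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, cls in (
            ("crop", CropConfig),
            ("centerline", CenterlineConfig),
            ("segmentation", SegmentationConfig),
            ("measurement", MeasurementConfig),
        ):
            if name in data:
                kwargs[name] = _strict_dataclass(cls, data.pop(name), name)
        if "registration" in data:
            reg = data.pop("registration")
            known_reg = {f.name for f in fields(RegistrationConfig)}
            unknown = set(reg) - known_reg
            if unknown:
                raise SchemaError(f"unknown registration config keys: {sorted(unknown)}")
            kwargs["registration"] = RegistrationConfig(**reg)
        kwargs.update(data)
        try:
            return PipelineConfig(**kwargs)
        except TypeError as exc:
            raise SchemaError(str(exc)) from exc

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _file_checksum(path) -> str:
    h = hashlib.sha256()
    if os.path.isdir(path):
        for name in sorted(os.listdir(path)):
            h.update(name.encode())
    else:
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    return h.hexdigest()[:16]


class _StageRunner:
    def __init__(self, out_dir):
        self.out_dir = out_dir
        self.intermediates: dict[str, str] = {}
        self.stage_log: list[dict] = []

    def run(self, stage: str, fn, **params):
        t0 = time.time()
        log.info("stage %s: starting (%s)", stage,
                 ", ".join(f"{k}={v}" for k, v in params.items()))
        try:
            result = fn()
        except AortrackError as exc:
            raise PipelineError(stage, str(exc), self.intermediates) from exc
        except (OSError, ValueError) as exc:
            raise PipelineError(stage, str(exc), self.intermediates) from exc
        dt = time.time() - t0
        self.stage_log.append(
            {"stage": stage, "seconds": round(dt, 3), "parameters": params}
        )
        log.info("stage %s: done in %.2f s", stage, dt)
        return result

    def record(self, name: str, path) -> str:
        self.intermediates[name] = str(path)
        return str(path)


def run_pipeline(
    baseline_path,
    followup_path,
    landmarks_path,
    config: PipelineConfig = PipelineConfig(),
    out_dir="aortrack_out",
) -> DiameterReport:
    """Execute the full baseline/follow-up dilatation quantification chain."""
    os.makedirs(out_dir, exist_ok=True)
    runner = _StageRunner(out_dir)
    t_start = time.time()

    baseline = runner.run("read_baseline", lambda: read_volume(baseline_path),
                          path=str(baseline_path))
    followup = runner.run("read_followup", lambda: read_volume(followup_path),
                          path=str(followup_path))

    def read_annotations():
        with open(landmarks_path) as fh:
            return {k: np.asarray(v, dtype=float) for k, v in json.load(fh).items()}

    annotations = runner.run("read_landmarks", read_annotations,
                             path=str(landmarks_path))

    cc = config.crop
    if cc.z_lo is not None or cc.z_hi is not None:
        z_lo = cc.z_lo or 0
        z_hi = cc.z_hi if cc.z_hi is not None else baseline.voxels.shape[0]
        baseline = runner.run("crop_baseline", lambda: crop_z(baseline, z_lo, z_hi),
                              z_lo=z_lo, z_hi=z_hi)

    clc = config.centerline
    seed_point = clc.lumen_seed if clc.lumen_seed is not None else annotations["DESC"]

    model = runner.run(
        "lumen_model",
        lambda: fit_lumen_model(baseline, seed_point, clc.sample_radius),
        seed=list(np.round(np.asarray(seed_point, float), 1)),
    )

    def get_endpoints():
        if clc.start_point is not None and clc.end_point is not None:
            return np.asarray(clc.start_point, float), np.asarray(clc.end_point, float)
        root, desc = detect_endpoints(baseline, model, clc.ceiling_sigma)
        if clc.start_point is not None:
            root = np.asarray(clc.start_point, float)
        if clc.end_point is not None:
            desc = np.asarray(clc.end_point, float)
        return root, desc

    start, end = runner.run("endpoints", get_endpoints)

    def centerline_stage():
        path = extract_path(baseline, model, start, end, clc.ceiling_sigma)
        return recenter(path, baseline, model,
                        search_radius=clc.recenter_search_radius,
                        passes=clc.recenter_passes,
                        ceiling_sigma=clc.ceiling_sigma)

    cl = runner.run("centerline", centerline_stage,
                    ceiling_sigma=clc.ceiling_sigma)
    cl.save(runner.record("centerline", os.path.join(out_dir, "centerline.json")))

    sc = config.segmentation
    baseline_mesh = runner.run(
        "segment_baseline",
        lambda: surface.segment_baseline(
            baseline, cl,
            smoothing_sigma=sc.smoothing_sigma, rings_per_cm=sc.rings_per_cm,
            vertices_per_ring=sc.vertices_per_ring, levels=sc.levels,
            search_range=sc.baseline_search_range, iterations=sc.iterations,
            step=sc.step, smooth_weight=sc.smooth_weight,
        ),
        rings_per_cm=sc.rings_per_cm, vertices_per_ring=sc.vertices_per_ring,
    )
    baseline_mesh.save_json(
        runner.record("baseline_mesh", os.path.join(out_dir, "baseline_mesh.json")))
    baseline_mesh.save_ply(
        runner.record("baseline_mesh_ply", os.path.join(out_dir, "baseline_mesh.ply")))

    reg_cfg = config.registration
    if config.seed and reg_cfg.seed == 0:
        from dataclasses import replace

        reg_cfg = replace(reg_cfg, seed=config.seed)

    transform, aligned = runner.run(
        "register",
        lambda: registration.align_followup(baseline, followup, baseline_mesh, reg_cfg),
        bins=reg_cfg.bins, samples=reg_cfg.samples, levels=reg_cfg.levels,
        seed=reg_cfg.seed,
    )
    transform.save(runner.record("transform", os.path.join(out_dir, "transform.json")))
    if config.save_aligned_volume:
        write_volume(aligned,
                     runner.record("aligned", os.path.join(out_dir, "aligned.mha")))

    followup_mesh = runner.run(
        "segment_followup",
        lambda: surface.segment_followup(
            aligned, baseline_mesh, cl,
            smoothing_sigma=sc.smoothing_sigma,
            search_range=sc.followup_search_range, iterations=sc.iterations,
            step=sc.step, smooth_weight=sc.smooth_weight,
            threshold_window=sc.threshold_window,
        ),
        search_range=sc.followup_search_range,
    )
    followup_mesh.save_json(
        runner.record("followup_mesh", os.path.join(out_dir, "followup_mesh.json")))

    landmarks = runner.run("landmarks", lambda: build_landmarks(annotations, cl))
    landmarks.save(runner.record("landmark_planes",
                                 os.path.join(out_dir, "landmarks.json")))

    report = runner.run(
        "measure",
        lambda: measurement.measure_pair(baseline_mesh, followup_mesh, landmarks),
    )
    mc = config.measurement
    s_b, d_b = measurement.diameter_curve(baseline_mesh, cl, mc.curve_step, landmarks)
    s_f, d_f = measurement.diameter_curve(followup_mesh, cl, mc.curve_step, landmarks)
    # common arc-length grid for the two curves
    common = np.intersect1d(s_b, s_f)
    report.curves = {
        "arc_length_mm": common,
        "baseline_mm": d_b[np.isin(s_b, common)],
        "followup_mm": d_f[np.isin(s_f, common)],
    }
    dilatation_field(baseline_mesh, followup_mesh)
    baseline_mesh.save_ply(runner.record(
        "dilatation_mesh", os.path.join(out_dir, "dilatation_field.ply")))
    baseline_mesh.save_vtk(runner.record(
        "dilatation_mesh_vtk", os.path.join(out_dir, "dilatation_field.vtk")))

    report.metadata = {
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "inputs": {
            "baseline": {"path": str(baseline_path),
                         "sha256": _file_checksum(baseline_path)},
            "followup": {"path": str(followup_path),
                         "sha256": _file_checksum(followup_path)},
            "landmarks": {"path": str(landmarks_path),
                          "sha256": _file_checksum(landmarks_path)},
        },
        "stages": runner.stage_log,
        "total_seconds": round(time.time() - t_start, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    report.to_csv(os.path.join(out_dir, "report.csv"))
    report.to_json(os.path.join(out_dir, "report.json"))
    return report
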