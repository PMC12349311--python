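"""Staged pipeline orchestration: clip → indices → cluster → detect → report.

A run directory holds every intermediate and final product; ``manifest.json``
records the configuration snapshot, input digests and a checksum for each
output so deterministic stages can be verified (and skipped) on re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import areas, damage, indices, raster, validation, vigor

log = logging.getLogger(__name__)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    field_name: str = ""
    location: str = ""
    flight_date: str = ""
    institution: str = ""
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)       # path -> sha256
    stages: dict = field(default_factory=dict)       # stage -> iso timestamp
    outputs: dict = field(default_factory=dict)      # relpath -> sha256

    def register(self, workdir, *paths):
        for p in paths:
            rel = os.path.relpath(p, workdir)
            self.outputs[rel] = sha256_of(p)

    def stamp(self, stage, timestamp=None):
        self.stages[stage] = timestamp or time.strftime("%Y-%m-%dT%H:%M:%S")

    def save(self, workdir):
        with open(os.path.join(workdir, "manifest.json"), "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, workdir):
        with open(os.path.join(workdir, "manifest.json")) as fh:
            return cls(**json.load(fh))


DEFAULT_CONFIG = {
    "input": {"orthomosaic": "", "boundary": ""},
    "run": {"seed": 42},
    "indices": {"rescale": True, "exg_chromatic": False},
    "cluster": {"k": 5, "standardize": True, "sample": 0},
    "detect": {"fractions": [0.25, 0.25, 0.25, 0.25, 0.25]},
    "validate": {"n": 100, "min_spacing_m": 15.0, "seed": 45, "reference": ""},
    "report": {"field_name": "", "location": "", "flight_date": "",
               "institution": "", "timestamp": ""},
}


def load_config(path) -> dict:
    import tomllib
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, values in user.items():
        cfg.setdefault(section, {}).update(values)
    return cfg


def write_default_config(path, **report_fields) -> None:
    lines = []
    for section, values in DEFAULT_CONFIG.items():
        lines.append(f"[{section}]")
        for key, val in values.items():
            if section == "report" and key in report_fields:
                val = report_fields[key]
            if isinstance(val, bool):
                lines.append(f"{key} = {str(val).lower()}")
            elif isinstance(val, (int, float)):
                lines.append(f"{key} = {val}")
            elif isinstance(val, list):
                lines.append(f"{key} = {json.dumps(val)}")
            else:
                lines.append(f'{key} = "{val}"')
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


@dataclass
class PipelineResult:
    manifest: RunManifest
    ortho: raster.RGBOrthomosaic
    stack: indices.IndexStack
    vigor_raster: vigor.VigorClassRaster
    masks: damage.DamageMaskSet
    summary: areas.AreaSummary
    report: validation.ClassificationReport | None = None


def preprocess(cfg, workdir):
    """DD_02 stage: clip, normalize, compute indices, cluster, rank."""
    ortho_path = cfg["input"]["orthomosaic"]
    boundary_path = cfg["input"]["boundary"]
    for p, what in ((ortho_path, "orthomosaic"), (boundary_path, "boundary")):
        if not p or not os.path.exists(p):
            raise FileNotFoundError(f"{what} file not found: {p!r}")
    ortho = raster.load_orthomosaic(ortho_path)
    boundary = raster.load_boundary(boundary_path, crs=ortho.crs)
    clipped = raster.clip_to_boundary(ortho, boundary)
    raster.write_orthomosaic(os.path.join(workdir, "clipped.tif"), clipped)

    stack = indices.compute_index_stack(
        clipped, rescale=cfg["indices"]["rescale"],
        exg_chromatic=cfg["indices"]["exg_chromatic"])
    for name in indices.INDEX_NAMES + ("composite",):
        grid = getattr(stack, name).astype(np.float32)
        raster.write_single_band(os.path.join(workdir, f"index_{name}.tif"),
                                 grid, clipped.transform, clipped.crs,
                                 nodata=float("nan"))

    sample = cfg["cluster"]["sample"] or None
    vcr = vigor.classify_vigor(stack, k=cfg["cluster"]["k"],
                               seed=cfg["run"]["seed"],
                               standardize=cfg["cluster"]["standardize"],
                               sample_size=sample)
    vigor.write_class_raster(os.path.join(workdir, "vigor_classes.tif"), vcr,
                             clipped.transform, clipped.crs,
                             legend_path=os.path.join(workdir, "vigor_legend.csv"))
    return clipped, boundary, stack, vcr


def detect(cfg, workdir, stack, vcr, clipped):
    config = damage.ThresholdConfig(fraction_by_class=tuple(cfg["detect"]["fractions"]))
    masks = damage.detect_damage(stack.composite, vcr, config)
    for cid, m in enumerate(masks.per_class):
        raster.write_single_band(os.path.join(workdir, f"damage_class{cid}.tif"),
                                 m.astype(np.uint8), clipped.transform,
                                 clipped.crs, nodata=None)
    raster.write_single_band(os.path.join(workdir, "damage_all.tif"),
                             masks.aggregated.astype(np.uint8),
                             clipped.transform, clipped.crs, nodata=None)
    return masks


def validate(cfg, workdir, boundary, vcr, transform):
    ref_csv = cfg["validate"].get("reference", "")
    if not ref_csv:
        return None
    import pandas as pd
    ref = pd.read_csv(ref_csv)
    pts = ref[["x", "y"]].to_numpy(dtype=float)
    ref_labels = ref["label"].to_numpy(dtype=int)
    pred, kept = validation.extract_labels(vcr, transform, pts)
    report = validation.build_report(ref_labels[kept], pred,
                                     n_classes=vcr.n_classes)
    pointset = validation.ValidationPointSet(
        points=pts[kept], reference_labels=ref_labels[kept],
        predicted_labels=pred, seed=cfg["validate"]["seed"],
        min_spacing_m=cfg["validate"]["min_spacing_m"])
    validation.points_to_geojson(os.path.join(workdir, "validation_points.geojson"),
                                 pointset)
    validation.report_to_frame(report).to_csv(
        os.path.join(workdir, "validation_report.csv"), index=False)
    validation.plot_confusion(report, os.path.join(workdir, "confusion_matrix.png"))
    return report


def run_pipeline(cfg: dict, workdir: str) -> PipelineResult:
    """Execute the full workflow and return in-memory results plus a manifest."""
    os.makedirs(workdir, exist_ok=True)
    manifest = RunManifest(
        field_name=cfg["report"]["field_name"], location=cfg["report"]["location"],
        flight_date=cfg["report"]["flight_date"],
        institution=cfg["report"]["institution"], config=cfg)
    pinned = cfg["report"].get("timestamp") or None
    for p in (cfg["input"]["orthomosaic"], cfg["input"]["boundary"]):
        if p and os.path.exists(p):
            manifest.inputs[p] = sha256_of(p)

    clipped, boundary, stack, vcr = preprocess(cfg, workdir)
    manifest.stamp("preprocess", pinned)
    manifest.register(workdir, *(os.path.join(workdir, f) for f in
                                 ["clipped.tif", "index_exg.tif", "index_gli.tif",
                                  "index_mgrvi.tif", "index_composite.tif",
                                  "vigor_classes.tif", "vigor_legend.csv"]))

    masks = detect(cfg, workdir, stack, vcr, clipped)
    manifest.stamp("detect", pinned)
    manifest.register(workdir, *(os.path.join(workdir, f"damage_class{c}.tif")
                                 for c in range(vcr.n_classes)),
                      os.path.join(workdir, "damage_all.tif"))

    summary = areas.summarize(vcr, masks, raster.pixel_area_m2(clipped),
                              field_area_m2=boundary.area_m2)
    areas.to_frame(summary).to_csv(os.path.join(workdir, "area_summary.csv"),
                                   index=False)
    manifest.stamp("summarize", pinned)
    manifest.register(workdir, os.path.join(workdir, "area_summary.csv"))

    report = validate(cfg, workdir, boundary, vcr, clipped.transform)
    if report is not None:
        manifest.stamp("validate", pinned)
        manifest.register(workdir, os.path.join(workdir, "validation_report.csv"))

    from .reporting import render_reports
    render_reports(workdir, manifest, clipped, vcr, masks, timestamp=pinned)
    manifest.stamp("report", pinned)
    manifest.register(workdir, os.path.join(workdir, "report.html"),
                      os.path.join(workdir, "report.md"))
    manifest.save(workdir)
    return PipelineResult(manifest=manifest, ortho=clipped, stack=stack,
                          vigor_raster=vcr, masks=masks, summary=summary,
                          report=report)
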