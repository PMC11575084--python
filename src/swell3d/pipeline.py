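"""End-to-end swelling analysis on a T0/T1/T2 scan triplet.

Workflow: anonymize -> orient T0 into the canonical frame (landmarks, then an
optional ICP refinement against a supplied oriented reference surface) ->
register T1 and T2 onto oriented T0 by trimmed ICP -> build the ROI on
oriented T0 -> for every pair (T0-T1, T1-T2, T0-T2) compute the signed
distance field of the later against the earlier scan, its ROI mean/SD, and
the ROI-clipped closed-volume difference -> export colormaps, displacement
vectors and the quantitative report. Pair values are later-minus-earlier, so
swelling onset is positive and resolution negative.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from . import __version__
from .distances import (colormap_export, default_span,
                        displacement_vector_export, mean_linear_difference,
                        signed_distance_field, std_linear_difference)
from .errors import PipelineError, Swell3dError
from .mesh_io import anonymize, read_mesh
from .registration import (IcpParams, LandmarkSet, apply_transform,
                           icp_register, orient_by_landmarks)
from .roi import RoiSpec, clip_to_roi_solid, roi_from_landmarks
from .volumetry import mesh_volume

PAIRS = (("T0", "T1"), ("T1", "T2"), ("T0", "T2"))


class IcpSettings(BaseModel):
    max_iterations: int = 100
    rms_change_tolerance: float = 1e-4
    trim_fraction: float = Field(default=0.10, ge=0.0, lt=0.5)
    subsample_size: int = 5000

    def to_params(self, seed: int) -> IcpParams:
        return IcpParams(max_iterations=self.max_iterations,
                         rms_change_tolerance=self.rms_change_tolerance,
                         trim_fraction=self.trim_fraction,
                         subsample_size=self.subsample_size,
                         seed=seed)


class PipelineConfig(BaseModel):
    """Inputs and parameters of one swelling analysis run."""

    t0: str
    t1: str
    t2: str
    landmarks: str
    reference: Optional[str] = None     # pre-oriented reference surface for T0
    roi_spec: Optional[str] = None      # explicit RoiSpec JSON; default: landmarks
    icp: IcpSettings = IcpSettings()
    colormap_span_mm: Optional[float] = None
    out_dir: str = "swell3d_out"
    seed: int = 0

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib
            return cls.model_validate(tomllib.loads(text))
        return cls.model_validate(json.loads(text))

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)

    def sha256(self) -> str:
        """Hash of the analysis-relevant config (artifact destination excluded)."""
        payload = self.model_dump()
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class PairResult:
    pair: str
    linear_difference_mean_mm: float
    linear_difference_sd_mm: float
    volume_earlier_mm3: float
    volume_later_mm3: float
    volume_difference_mm3: float
    registration_rms_mm: float
    n_roi_vertices: int
    n_holes_filled_earlier: int
    n_holes_filled_later: int


@dataclass
class SwellingReport:
    pairs: dict                    # label -> PairResult
    provenance: dict

    def to_json_dict(self) -> dict:
        return {"pairs": {k: vars(v) for k, v in self.pairs.items()},
                "provenance": self.provenance}

    def canonical_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True, indent=2) + "\n"

    def volume_additivity_residual(self) -> float:
        """| (T0-T2) - [(T0-T1) + (T1-T2)] | relative to |T0-T2| (or absolute
        when the T0-T2 difference is ~0)."""
        d01 = self.pairs["T0-T1"].volume_difference_mm3
        d12 = self.pairs["T1-T2"].volume_difference_mm3
        d02 = self.pairs["T0-T2"].volume_difference_mm3
        resid = abs(d02 - (d01 + d12))
        return resid / abs(d02) if abs(d02) > 1.0 else resid


def run_pipeline(config: PipelineConfig, write_artifacts: bool = True
                 ) -> SwellingReport:
    """Execute the full workflow; returns the report (and writes artifacts)."""
    out_dir = Path(config.out_dir)
    if write_artifacts:
        out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage, message):
        log_lines.append(f"[{stage}] {message}")

    def run_stage(stage, func, path=None):
        try:
            return func()
        except Swell3dError as exc:
            raise PipelineError(stage, str(exc), path) from exc

    meshes = {}
    for label, path in (("T0", config.t0), ("T1", config.t1), ("T2", config.t2)):
        meshes[label] = run_stage("read", lambda p=path: read_mesh(p), path)
        log("read", f"{label}: {path} ({meshes[label].n_vertices} vertices, "
                    f"{meshes[label].n_faces} faces)")

    meshes = {k: anonymize(m) for k, m in meshes.items()}
    log("anonymize", "metadata and color attributes stripped from all scans")

    landmarks = run_stage("landmarks",
                          lambda: LandmarkSet.load(config.landmarks),
                          config.landmarks)
    orient = run_stage("orient", lambda: orient_by_landmarks(landmarks),
                       config.landmarks)
    registered = {"T0": apply_transform(meshes["T0"], orient)}
    oriented_landmarks = landmarks.transformed(orient)
    rms = {"T0": 0.0}
    log("orient", "T0 oriented by Frankfurt/midsagittal landmarks")

    if config.reference is not None:
        reference = run_stage("reference", lambda: read_mesh(config.reference),
                              config.reference)
        res = run_stage("orient", lambda: icp_register(
            registered["T0"], reference, config.icp.to_params(config.seed)))
        registered["T0"] = apply_transform(registered["T0"], res.transform)
        oriented_landmarks = oriented_landmarks.transformed(res.transform)
        rms["T0"] = res.rms
        log("orient", f"T0 refined against reference (RMS {res.rms:.4f} mm)")

    for offset, label in ((1, "T1"), (2, "T2")):
        res = run_stage("register", lambda lbl=label, off=offset: icp_register(
            meshes[lbl], registered["T0"], config.icp.to_params(config.seed + off)))
        registered[label] = apply_transform(meshes[label], res.transform)
        rms[label] = res.rms
        log("register", f"{label} -> T0 trimmed ICP: RMS {res.rms:.4f} mm, "
                        f"{res.n_iterations} iterations, converged={res.converged}")

    if config.roi_spec is not None:
        roi = run_stage("roi", lambda: RoiSpec.load(config.roi_spec),
                        config.roi_spec)
    else:
        roi = run_stage("roi", lambda: roi_from_landmarks(oriented_landmarks))
    log("roi", f"{roi.label}: {len(roi.half_spaces)} boundary planes")

    # per-mesh ROI volume, computed once and shared by every pair; the solid
    # intersection caps every clip plane exactly, so cap geometry cancels
    # between scans in the later-minus-earlier difference
    clipped_stats = {}
    for label, mesh in registered.items():
        def volume_of(m=mesh):
            solid, n_filled = clip_to_roi_solid(m, roi)
            result = mesh_volume(solid)
            return result.volume, n_filled
        clipped_stats[label] = run_stage("volume", volume_of)
        log("volume", f"{label}: ROI volume {clipped_stats[label][0]:.2f} mm^3 "
                      f"({clipped_stats[label][1]} hole(s) closed)")

    pairs = {}
    for earlier, later in PAIRS:
        label = f"{earlier}-{later}"
        field = run_stage("distance", lambda e=earlier, l=later: signed_distance_field(
            registered[l], registered[e], pair_label=label))
        mean = run_stage("distance", lambda f=field: mean_linear_difference(f, roi))
        sd = run_stage("distance", lambda f=field: std_linear_difference(f, roi))
        n_roi = int(roi.contains(field.base.vertices).sum())
        v_earlier, holes_earlier = clipped_stats[earlier]
        v_later, holes_later = clipped_stats[later]
        pairs[label] = PairResult(
            pair=label,
            linear_difference_mean_mm=mean,
            linear_difference_sd_mm=sd,
            volume_earlier_mm3=v_earlier,
            volume_later_mm3=v_later,
            volume_difference_mm3=v_later - v_earlier,
            registration_rms_mm=max(rms[earlier], rms[later]),
            n_roi_vertices=n_roi,
            n_holes_filled_earlier=holes_earlier,
            n_holes_filled_later=holes_later,
        )
        log("pair", f"{label}: mean {mean:+.3f} mm, "
                    f"dV {v_later - v_earlier:+.2f} mm^3")
        if write_artifacts:
            span = config.colormap_span_mm or default_span(field)
            colormap_export(field, out_dir / f"colormap_{label}.ply", span)
            displacement_vector_export(field, out_dir / f"vectors_{label}.vtk")

    report = SwellingReport(
        pairs=pairs,
        provenance={"config_sha256": config.sha256(),
                    "package_version": __version__,
                    "seed": config.seed},
    )
    if write_artifacts:
        (out_dir / "report.json").write_text(report.canonical_json())
        report_to_csv(report, out_dir / "report.csv")
        roi.save(out_dir / "roi.json")
        (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return report


CSV_FIELDS = ("pair", "linear_difference_mean_mm", "linear_difference_sd_mm",
              "volume_earlier_mm3", "volume_later_mm3", "volume_difference_mm3",
              "registration_rms_mm", "n_roi_vertices",
              "n_holes_filled_earlier", "n_holes_filled_later")


def report_to_csv(report: SwellingReport, path) -> None:
    """One row per pair; floats at full precision; stable header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_FIELDS)
        for label in (f"{a}-{b}" for a, b in PAIRS):
            row = report.pairs[label]
            writer.writerow([repr(v) if isinstance(v, float) else v
                             for v in (getattr(row, f) for f in CSV_FIELDS)])
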