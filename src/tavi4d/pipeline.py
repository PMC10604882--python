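"""End-to-end orchestration: study in, masks + metrics + manifest out.

Each phase runs the stage chain

    frame mask -> filling -> principal axis -> root mask -> outflow
    orientation -> reformat -> CSA profile / 3D-object metrics

with every intermediate optionally written to the output directory, and a
manifest recording the configuration and per-stage status.  The analysis
path is seed-free and deterministic; identical inputs and configuration
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .axis_reformat import AxisFrame, build_rotation, orient_outflow, principal_axis, reformat
from .frame_filling import FillingParams, fill_largest_cavity
from .frame_segmentation import SegmentationParams, segment_frame
from .image_model import BinaryMask, ScalarVolume, Study4D, read_dicom_series, read_volume, write_volume
from .metrics import (
    CohortSummary,
    PatientResult,
    PlaneSet,
    cohort_summary,
    csa_profile,
    displacement_series,
    locate_planes,
    prosthesis_state,
)
from .root_segmentation import PostprocessParams, SeedParams, segment_root

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_cohort"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline (defaults: the published
    clinical operating point; see each stage's docs for units)."""

    th1: float = 800.0
    th2: int = 11000
    density_cutoff: float = 0.5
    closing_radius_mm: float = 3.0
    fill_iterations: int = 6
    r1: float = 2.0
    r2: float = 40.0
    grow_mm: float = 1.0
    shrink_mm: float = 2.0
    open_radius_mm: float = 3.0
    median_radius_vox: int = 1
    h_step: float = 1.0
    out_spacing: float = 0.0  # 0 -> input in-plane spacing
    segment_root_flag: bool = True
    outflow_sign: int = 1  # fallback when the lumen is symmetric/absent
    random_seed: int = 0
    output_dir: str = ""

    # ---- sub-parameter bundles ------------------------------------------
    def seg_params(self) -> SegmentationParams:
        return SegmentationParams(
            th1=self.th1, th2=self.th2, density_cutoff=self.density_cutoff,
            closing_radius_mm=self.closing_radius_mm,
        )

    def fill_params(self) -> FillingParams:
        return FillingParams(
            closing_radius_mm=self.closing_radius_mm, iterations=self.fill_iterations
        )

    def seed_params(self) -> SeedParams:
        return SeedParams(r1=self.r1, r2=self.r2)

    def post_params(self) -> PostprocessParams:
        return PostprocessParams(
            grow_mm=self.grow_mm, shrink_mm=self.shrink_mm,
            open_radius_mm=self.open_radius_mm,
            median_radius_vox=self.median_radius_vox,
        )

    # ---- plain-text serialization (key=value) ---------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: type(getattr(cls(), f.name)) for f in cls.__dataclass_fields__.values()}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            k, v = k.strip(), v.strip()
            if k not in types:
                raise ValueError(f"unknown config key: {k}")
            t = types[k]
            kwargs[k] = (v.lower() in ("1", "true", "yes")) if t is bool else t(v)
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything computed for one study (one patient)."""

    patient_id: str
    config: PipelineConfig
    frame_masks: list = field(default_factory=list)
    filling_masks: list = field(default_factory=list)
    root_masks: list = field(default_factory=list)
    axes: list = field(default_factory=list)
    states: list = field(default_factory=list)
    displacements: np.ndarray = field(default_factory=lambda: np.array([]))
    profiles: list = field(default_factory=list)
    planes: PlaneSet = field(default_factory=PlaneSet)
    manifest: dict = field(default_factory=dict)

    def to_patient_result(self, model: str = "unknown") -> PatientResult:
        return PatientResult(
            patient_id=self.patient_id, model=model, states=self.states,
            displacements=list(self.displacements), profiles=self.profiles,
            planes=self.planes,
        )

    def series_dict(self) -> dict:
        return {
            "patient": self.patient_id,
            "V_mm3": [s.V for s in self.states],
            "c_mm": [list(map(float, s.c)) for s in self.states],
            "alpha_deg": [list(map(float, s.alpha)) for s in self.states],
            "d_mm": [float(x) for x in self.displacements],
            "planes": {"h1": self.planes.h1, "h2": self.planes.h2, "h3": self.planes.h3},
        }

    def profiles_frame(self, model: str = "unknown") -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            for i, h in enumerate(p.h_grid):
                rows.append(
                    {
                        "patient": self.patient_id,
                        "model": model,
                        "t": p.t,
                        "h_percent": float(h),
                        "csa_p_mm2": float(p.csa_p[i]),
                        "csa_a_mm2": float(p.csa_a[i]) if p.csa_a is not None else np.nan,
                        "dcsa_mm2": float(p.dcsa[i]) if p.dcsa is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def _load_study(study: "Study4D | str | Path") -> Study4D:
    if isinstance(study, Study4D):
        return study
    path = Path(study)
    if path.is_dir():
        niftis = sorted(path.glob("*.nii*"))
        if niftis:
            return Study4D(phases=tuple(read_volume(p) for p in niftis))
        return read_dicom_series(path)
    return Study4D(phases=(read_volume(path),))


def run_pipeline(study: "Study4D | str | Path",
                 config: PipelineConfig = PipelineConfig(),
                 patient_id: str = "patient") -> PipelineResult:
    """Run every stage on every phase; abort on the first stage failure with
    the stage name and phase index in the error message."""
    study = _load_study(study)
    res = PipelineResult(patient_id=patient_id, config=config)
    stages = []
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    out_spacing = config.out_spacing if config.out_spacing > 0 else None

    def run_stage(name, t, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as e:
            stages.append({"stage": name, "phase": t, "status": f"failed: {e}",
                           "elapsed_s": round(time.perf_counter() - t0, 3)})
            res.manifest = _manifest(config, stages)
            raise RuntimeError(f"stage '{name}' failed on phase {t}: {e}") from e
        stages.append({"stage": name, "phase": t, "status": "ok",
                       "elapsed_s": round(time.perf_counter() - t0, 3)})
        return out

    for t, vol in enumerate(study):
        frame = run_stage("segment_frame", t, lambda: segment_frame(vol, config.seg_params()))
        filling = run_stage("fill_frame", t,
                            lambda: fill_largest_cavity(frame, config.fill_params()))
        axis = run_stage(
            "principal_axis", t,
            lambda: build_rotation(principal_axis(filling), vol.physical_center()),
        )
        root = None
        if config.segment_root_flag:
            root = run_stage(
                "segment_root", t,
                lambda: segment_root(vol, filling, frame, axis,
                                     config.seed_params(), config.post_params()),
            )
        axis = run_stage(
            "orient_outflow", t,
            lambda: orient_outflow(frame, root, axis, fallback_sign=config.outflow_sign),
        )
        fill_ref = run_stage("reformat", t, lambda: reformat(filling, axis, out_spacing))
        root_ref = reformat(root, axis, out_spacing) if root is not None else None
        profile = run_stage(
            "csa_profile", t,
            lambda: csa_profile(fill_ref, root_ref, axis, h_step=config.h_step, t=t),
        )
        state = run_stage("metrics", t, lambda: prosthesis_state(frame, filling, axis, t))

        res.frame_masks.append(frame)
        res.filling_masks.append(filling)
        res.root_masks.append(root)
        res.axes.append(axis)
        res.profiles.append(profile)
        res.states.append(state)
        if out_dir:
            write_volume(frame, out_dir / f"frame_t{t}.nii.gz")
            write_volume(filling, out_dir / f"fill_t{t}.nii.gz")
            if root is not None:
                write_volume(root, out_dir / f"root_t{t}.nii.gz")
            axis.save(out_dir / f"axis_t{t}.json")

    if len(res.states) >= 2:
        res.displacements = displacement_series(res.states)
    res.planes = locate_planes(res.profiles)
    res.manifest = _manifest(config, stages)
    if out_dir:
        (out_dir / "series.json").write_text(json.dumps(res.series_dict(), indent=2))
        res.profiles_frame().to_csv(out_dir / "profiles.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(res.manifest, indent=2))
    return res


def _manifest(config: PipelineConfig, stages: list) -> dict:
    return {
        "tool": "tavi4d",
        "version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "stages": stages,
    }


def run_cohort(studies: list, model_labels: list,
               config: PipelineConfig = PipelineConfig(),
               patient_ids: list | None = None) -> tuple:
    """Run all patients and aggregate per device model.

    Individual failures are excluded from the summary and reported in the
    returned warning records, not fatal.
    """
    if patient_ids is None:
        patient_ids = [f"patient{i:02d}" for i in range(len(studies))]
    results, labels, failures = [], [], []
    for pid, study, model in zip(patient_ids, studies, model_labels):
        try:
            r = run_pipeline(study, config, patient_id=pid)
        except Exception as e:
            failures.append({"patient": pid, "model": model, "error": str(e)})
            warnings.warn(f"patient {pid} excluded: {e}")
            continue
        results.append(r.to_patient_result(model))
        labels.append(model)
    if not results:
        raise RuntimeError(f"no patient completed the pipeline; failures: {failures}")
    summary = cohort_summary(results, labels)
    return summary, failures
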