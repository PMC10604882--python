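"""Prosthesis, implant, and cohort metrics.

Per phase t the prosthesis is characterized by its inner volume V(t)
(volume of the filling segment), the frame center of mass c(t), the angles
alpha(t) between the principal axis and the coordinate axes, and the
frame-relative displacement d(t) = |c(t) - c(t-1)|.  Cross-sectional areas
are measured on the reformatted (axis-aligned) stacks as functions of the
normalized height h, running 0% at the outflow tip to 100% at the inflow
tip; the implant is characterized by dCSA(t,h) = CSAa - CSAp, the free
lumen area between device and aortic wall.  Cohort summaries aggregate
mean and cycle range (max - min) of each series per device model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .axis_reformat import AxisFrame
from .image_model import BinaryMask

__all__ = [
    "ProsthesisState",
    "CSAProfile",
    "PlaneSet",
    "PatientResult",
    "CohortSummary",
    "prosthesis_state",
    "displacement_series",
    "csa_profile",
    "locate_planes",
    "cohort_summary",
]


@dataclass(frozen=True)
class ProsthesisState:
    """3D-object metrics of one phase."""

    t: int
    V: float  # inner volume, mm^3
    c: np.ndarray  # frame center of mass, mm
    alpha: np.ndarray  # (alpha_x, alpha_y, alpha_z), degrees

    def __post_init__(self):
        if self.V <= 0:
            raise ValueError("inner volume must be positive")


@dataclass
class CSAProfile:
    """Area-vs-height curves of one phase (areas mm^2, h in % of length)."""

    t: int
    h_grid: np.ndarray
    csa_p: np.ndarray
    csa_a: np.ndarray | None = None
    dcsa: np.ndarray | None = None
    axial_length_mm: float = 0.0
    slice_thickness_mm: float = 0.0

    def at(self, h: float, which: str = "csa_p") -> float:
        arr = getattr(self, which)
        if arr is None:
            raise ValueError(f"{which} was not computed for this profile")
        return float(np.interp(h, self.h_grid, arr))

    def integral_mm3(self) -> float:
        """Volume implied by the CSA curve: trapezoid over the axial length
        plus the half-slice the tips extend beyond the first/last centers."""
        h_mm = self.h_grid / 100.0 * self.axial_length_mm
        end = 0.5 * (self.csa_p[0] + self.csa_p[-1]) * self.slice_thickness_mm
        return float(np.trapezoid(self.csa_p, h_mm) + end)


@dataclass(frozen=True)
class PlaneSet:
    """Analysis planes: outflow h1, maximum-diameter h2, inflow h3 (%)."""

    h1: float = 0.0
    h2: float = 0.0
    h3: float = 100.0

    def __post_init__(self):
        if not (self.h1 <= self.h2 <= self.h3):
            raise ValueError("planes must satisfy h1 <= h2 <= h3")


@dataclass
class PatientResult:
    """Full per-patient series, input to the cohort aggregation."""

    patient_id: str
    model: str
    states: list = field(default_factory=list)
    displacements: list = field(default_factory=list)
    profiles: list = field(default_factory=list)
    planes: PlaneSet = field(default_factory=PlaneSet)


def prosthesis_state(frame: BinaryMask, filling: BinaryMask, axis: AxisFrame,
                     t: int = 0) -> ProsthesisState:
    """V from the filling, c from the frame, alpha from the axis director."""
    if not (frame.voxels.any() and filling.voxels.any()):
        raise ValueError("frame and filling masks must be nonempty")
    alpha = np.rad2deg(np.arccos(np.clip(np.abs(axis.v), 0.0, 1.0)))
    return ProsthesisState(t=t, V=filling.volume_mm3, c=frame.centroid_mm(), alpha=alpha)


def displacement_series(states: list) -> np.ndarray:
    """d(t) = |c(t) - c(t-1)| in mm for t = 1..T-1."""
    if len(states) < 2:
        raise ValueError("displacement needs at least two phases")
    c = np.array([s.c for s in states])
    return np.linalg.norm(np.diff(c, axis=0), axis=1)


def csa_profile(filling_reformatted: BinaryMask,
                root_reformatted: BinaryMask | None,
                orientation: AxisFrame, h_step: float = 1.0,
                t: int = 0, max_gap: int = 2) -> CSAProfile:
    """Slice the axis-aligned stacks and map slice areas onto the h grid.

    The filling's occupied z range defines the tips; ``orientation_sign``
    decides which tip is h=0 (the +z end when the sign is +1, because the
    reformat maps +v onto +z).
    """
    vox = filling_reformatted.voxels
    counts = vox.sum(axis=(0, 1))
    occupied = np.flatnonzero(counts > 0)
    if occupied.size < 2:
        raise ValueError("filling occupies fewer than 2 slices after reformat")
    k0, k1 = int(occupied[0]), int(occupied[-1])
    interior = counts[k0 : k1 + 1]
    longest = _longest_zero_run(interior)
    if longest > max_gap:
        raise ValueError(
            f"filling is broken: {longest} consecutive empty interior slices"
        )
    pix_area = float(filling_reformatted.spacing[0] * filling_reformatted.spacing[1])
    ks = np.arange(k0, k1 + 1)
    if orientation.orientation_sign >= 0:
        h_slices = (k1 - ks) / (k1 - k0) * 100.0  # outflow at +z
    else:
        h_slices = (ks - k0) / (k1 - k0) * 100.0
    nonzero = interior > 0  # bridge allowed 1-2 slice gaps by interpolation
    order = np.argsort(h_slices[nonzero])
    h_sorted = h_slices[nonzero][order]
    area_p = (interior[nonzero] * pix_area)[order]

    h_grid = np.arange(0.0, 100.0 + 0.5 * h_step, h_step)
    csa_p = np.interp(h_grid, h_sorted, area_p)
    length = (k1 - k0) * float(filling_reformatted.spacing[2])

    csa_a = dcsa = None
    if root_reformatted is not None:
        if root_reformatted.shape != filling_reformatted.shape:
            raise ValueError("root and filling reformats are on different grids")
        counts_a = root_reformatted.voxels.sum(axis=(0, 1))[k0 : k1 + 1]
        area_a = (counts_a[nonzero] * pix_area)[order]
        csa_a = np.interp(h_grid, h_sorted, area_a)
        dcsa = csa_a - csa_p
    return CSAProfile(t=t, h_grid=h_grid, csa_p=csa_p, csa_a=csa_a, dcsa=dcsa,
                      axial_length_mm=length,
                      slice_thickness_mm=float(filling_reformatted.spacing[2]))


def _longest_zero_run(x: np.ndarray) -> int:
    best = cur = 0
    for v in x:
        cur = cur + 1 if v == 0 else 0
        best = max(best, cur)
    return best


def locate_planes(profiles: list, tip_band_percent: float = 3.0,
                  plateau_rel_tol: float = 5e-3,
                  plateau_span_frac: float = 0.3) -> PlaneSet:
    """h2 = argmax over h of the time-averaged equivalent diameter
    2 sqrt(CSA/pi).

    Near-ties resolve toward the outflow: when the heights within
    ``plateau_rel_tol`` of the maximum span a large fraction of the device
    (an essentially uniform caliber, sub-voxel differences only), the
    maximum-diameter plane is taken at the outflow, h2 = h1; likewise a
    maximum inside the low-confidence tip band snaps to h2 = 0
    (outflow-maximal devices)."""
    if not profiles:
        raise ValueError("at least one profile is required")
    h = profiles[0].h_grid
    mean_diam = np.mean(
        [2.0 * np.sqrt(np.maximum(p.csa_p, 0.0) / np.pi) for p in profiles], axis=0
    )
    smooth = uniform_filter1d(mean_diam, size=5, mode="nearest")
    near_max = smooth >= smooth.max() * (1.0 - plateau_rel_tol)
    if near_max.mean() >= plateau_span_frac:
        h2 = 0.0
    else:
        h2 = float(h[int(np.argmax(smooth))])
        if h2 <= tip_band_percent:
            h2 = 0.0
    return PlaneSet(h1=0.0, h2=h2, h3=100.0)


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------

def _mean_delta(series) -> tuple:
    a = np.asarray(series, dtype=float)
    return float(a.mean()), float(a.max() - a.min())


@dataclass
class CohortSummary:
    """Per-model aggregate: tidy frame (model, metric, mean, sd, n) plus a
    printable wide table with 'mean ± sd' cells."""

    tidy: pd.DataFrame
    table: pd.DataFrame


def _patient_scalars(res: PatientResult) -> dict:
    out = {}
    out["Vm"], out["Vrange"] = _mean_delta([s.V for s in res.states])
    if len(res.displacements):
        out["dm"], out["drange"] = _mean_delta(res.displacements)
    planes = {"h1": res.planes.h1, "h2": res.planes.h2, "h3": res.planes.h3}
    has_root = all(p.dcsa is not None for p in res.profiles)
    for name, hv in planes.items():
        csa_series = [p.at(hv, "csa_p") for p in res.profiles]
        out[f"CSA({name})m"], out[f"CSA({name})range"] = _mean_delta(csa_series)
        if has_root:
            d_series = [p.at(hv, "dcsa") for p in res.profiles]
            out[f"dCSA({name})m"], out[f"dCSA({name})range"] = _mean_delta(d_series)
    return out


def cohort_summary(per_patient_results: list,
                   model_labels: list | None = None) -> CohortSummary:
    """Mean ± sample sd of each per-patient scalar, grouped by device model.

    h2 rows are omitted for models whose h2 coincides with h1 (the
    outflow-maximal convention prints no separate h2 entry).
    """
    if not per_patient_results:
        raise ValueError("no patient results to aggregate")
    if model_labels is None:
        model_labels = [r.model for r in per_patient_results]
    rows = []
    for res, model in zip(per_patient_results, model_labels):
        rec = {"patient": res.patient_id, "model": model}
        rec.update(_patient_scalars(res))
        rec["_h2_is_h1"] = res.planes.h2 == res.planes.h1
        rows.append(rec)
    df = pd.DataFrame(rows)

    tidy_rows = []
    for model, grp in df.groupby("model", sort=True):
        drop_h2 = bool(grp["_h2_is_h1"].all())
        for metric in [c for c in grp.columns if c not in ("patient", "model", "_h2_is_h1")]:
            if drop_h2 and "(h2)" in metric:
                continue
            vals = grp[metric].dropna()
            if vals.empty:
                continue
            tidy_rows.append(
                {
                    "model": model,
                    "metric": metric,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": int(len(vals)),
                }
            )
    tidy = pd.DataFrame(tidy_rows)

    cells = {}
    for model, grp in tidy.groupby("model", sort=True):
        col = {"n": f"{int(grp['n'].max())}"}
        for _, r in grp.iterrows():
            sd = "" if np.isnan(r["sd"]) else f" ± {r['sd']:.2f}"
            col[r["metric"]] = f"{r['mean']:.2f}{sd}"
        cells[model] = col
    table = pd.DataFrame(cells).fillna("–")
    return CohortSummary(tidy=tidy, table=table)
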