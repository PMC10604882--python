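"""Principal-axis estimation and oblique reformat of the study.

The deployed prosthesis is generally tilted with respect to the scanner
axes.  The filling segment's principal inertia axis gives the device
director vector v; the rotation that maps v onto z = (0,0,1) is built from
the tilt angle

    theta = arccos( v . z / |v||z| )

about the axis

    n = v x z / |v x z|

(Rodrigues construction, applied about the study center).  Resampling the
study with this rotation yields image planes orthogonal to the device —
the geometry every cross-sectional measurement relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .image_model import BinaryMask, ScalarVolume

__all__ = [
    "AxisFrame",
    "principal_axis",
    "tilt_angle",
    "rotation_axis",
    "build_rotation",
    "reformat",
    "orient_outflow",
]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class AxisFrame:
    """Principal-axis frame: director v, tilt theta, rotation axis n, and the
    rotation R about ``rotation_center`` taking v to z."""

    v: np.ndarray
    theta: float  # radians
    n: np.ndarray
    rotation_center: np.ndarray
    R: np.ndarray
    orientation_sign: int = 1  # +1: outflow (h=0) at the +v end

    def to_dict(self) -> dict:
        return {
            "v": list(map(float, self.v)),
            "theta_deg": float(np.rad2deg(self.theta)),
            "n": list(map(float, self.n)),
            "rotation_center_mm": list(map(float, self.rotation_center)),
            "R_row_major": [float(x) for x in self.R.flatten()],
            "orientation_sign": int(self.orientation_sign),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AxisFrame":
        return cls(
            v=np.array(d["v"], float),
            theta=float(np.deg2rad(d["theta_deg"])),
            n=np.array(d["n"], float),
            rotation_center=np.array(d["rotation_center_mm"], float),
            R=np.array(d["R_row_major"], float).reshape(3, 3),
            orientation_sign=int(d.get("orientation_sign", 1)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AxisFrame":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _canonicalize(v: np.ndarray) -> np.ndarray:
    """Flip sign so the z component (ties: x, then y) is positive."""
    for c in (2, 0, 1):
        if abs(v[c]) > 1e-12:
            return v if v[c] > 0 else -v
    return v


def principal_axis(filling: BinaryMask, min_voxels: int = 100,
                   min_elongation: float = 1.2, refine_iters: int = 2) -> np.ndarray:
    """Principal inertia direction of the filling voxel cloud in mm.

    The PCA direction is then polished by fitting a line through axial
    slab centroids (central 90% of the extent), which cancels the small
    bias that surface voxelization asymmetries induce in the raw inertia
    axis of a tube.
    """
    idx = np.argwhere(filling.voxels)
    if len(idx) < min_voxels:
        raise ValueError(f"filling has only {len(idx)} voxels (< {min_voxels})")
    pts = filling.index_to_physical(idx)
    pts = pts - pts.mean(axis=0)
    w, V = np.linalg.eigh(pts.T @ pts / len(pts))
    if w[-1] / max(w[-2], 1e-12) <= min_elongation:
        raise ValueError(
            f"ambiguous axis: inertia eigenvalue ratio {w[-1] / w[-2]:.3f} "
            f"<= {min_elongation} (near-isotropic filling)"
        )
    v = V[:, -1]
    q = 0.25 * float(min(filling.spacing))  # slab quantum, sub-voxel
    for _ in range(refine_iters):
        # quantize projections and offset the edges so slab boundaries never
        # cut through a single voxel plane (which would bias the centroids)
        s = np.round((pts @ v) / q) * q
        lo, hi = np.percentile(s, [5.0, 95.0])
        edges = np.linspace(lo - 0.5 * q, hi + 0.5 * q, 16)
        cents = []
        for a, b in zip(edges[:-1], edges[1:]):
            sel = (s >= a) & (s < b)
            if sel.sum() >= 10:
                cents.append(pts[sel].mean(axis=0))
        if len(cents) < 3:
            break
        cents = np.asarray(cents)
        cents -= cents.mean(axis=0)
        _, Vc = np.linalg.eigh(cents.T @ cents / len(cents))
        v_new = Vc[:, -1]
        v = v_new if np.dot(v_new, v) >= 0 else -v_new
    return _canonicalize(v)


def tilt_angle(v: np.ndarray) -> float:
    """Angle between the director vector and the grid z axis, radians."""
    v = np.asarray(v, float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("zero director vector")
    return float(np.arccos(np.clip(v[2] / nv, -1.0, 1.0)))


def rotation_axis(v: np.ndarray) -> np.ndarray:
    """Unit v x z.

    Degenerate cases: for v parallel to z the identity-rotation convention
    applies and z itself is returned; for v antiparallel the cross product
    also vanishes and any transverse axis serves — x is the convention.
    """
    v = np.asarray(v, float)
    c = np.cross(v, _Z)
    nc = np.linalg.norm(c)
    if nc < 1e-12:
        return np.array([1.0, 0.0, 0.0]) if v[2] < 0 else _Z.copy()
    return c / nc


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def build_rotation(v: np.ndarray, rotation_center: np.ndarray) -> AxisFrame:
    """Axis-angle rotation by theta about n that maps v onto z."""
    v = np.asarray(v, float)
    v = v / np.linalg.norm(v)
    theta = tilt_angle(v)
    n = rotation_axis(v)
    R = np.eye(3) if theta < 1e-12 else _rodrigues(n, theta)
    return AxisFrame(v=v, theta=theta, n=n,
                     rotation_center=np.asarray(rotation_center, float), R=R)


def reformat(volume: ScalarVolume, frame: AxisFrame,
             out_spacing: float | None = None) -> ScalarVolume:
    """Resample so the principal axis is grid-aligned with z.

    Intensities are interpolated trilinearly, masks nearest-neighbour; the
    output grid is isotropic in-plane (``out_spacing`` defaults to the input
    in-plane spacing) and covers the rotated input bounding box.
    """
    is_mask = isinstance(volume, BinaryMask)
    if out_spacing is None:
        out_spacing = float(np.mean(volume.spacing[:2]))
    sp = np.array([out_spacing, out_spacing, out_spacing])

    c = frame.rotation_center
    # forward map p -> R (p - c) + c ; bounding box from the 8 input corners
    shape = np.array(volume.shape, float) - 1.0
    corners = np.array(
        [[i, j, k] for i in (0, shape[0]) for j in (0, shape[1]) for k in (0, shape[2])]
    )
    phys = volume.index_to_physical(corners)
    rot = (phys - c) @ frame.R.T + c
    lo, hi = rot.min(axis=0), rot.max(axis=0)
    size = np.maximum(np.ceil((hi - lo) / sp).astype(int) + 1, 2)

    img = volume.to_sitk()
    if is_mask:
        img = sitk.Cast(img, sitk.sitkUInt8)
    tf = sitk.AffineTransform(3)
    tf.SetMatrix(tuple(frame.R.T.flatten()))  # resampling needs output->input
    tf.SetCenter(tuple(c))
    out = sitk.Resample(
        img,
        [int(s) for s in size],
        tf,
        sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear,
        [float(x) for x in lo],
        [float(s) for s in sp],
        (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        0.0,
        sitk.sitkUInt8 if is_mask else sitk.sitkFloat32,
    )
    res = ScalarVolume.from_sitk(out)
    if is_mask:
        return BinaryMask.like(res, res.voxels > 0)
    return res


def _slab_area(root: BinaryMask, axis_v: np.ndarray, s0: float,
               center: np.ndarray, half_mm: float = 1.0) -> float:
    """Approximate lumen CSA (mm^2) in the slab s in [s0-half, s0+half]."""
    idx = np.argwhere(root.voxels)
    if len(idx) == 0:
        return 0.0
    s = (root.index_to_physical(idx) - center) @ axis_v
    n_in = int(np.count_nonzero(np.abs(s - s0) <= half_mm))
    return n_in * root.voxel_volume / (2.0 * half_mm)


def orient_outflow(frame_mask: BinaryMask, root_mask: BinaryMask | None,
                   axis: AxisFrame, beyond_mm: float = 5.0,
                   fallback_sign: int | None = None) -> AxisFrame:
    """Resolve which tip is the outflow (h = 0).

    The ascending aorta continues past the outflow tip, so the tip with the
    larger aortic-lumen CSA in the plane ``beyond_mm`` past it is labelled
    outflow.  Without a root mask, or when the two sides are symmetric, the
    caller-supplied ``fallback_sign`` is used.
    """
    if root_mask is None:
        if fallback_sign is None:
            raise ValueError("no root mask: an explicit orientation flag is required")
        return replace(axis, orientation_sign=int(fallback_sign))
    idx = np.argwhere(frame_mask.voxels)
    c = frame_mask.centroid_mm()
    s = (frame_mask.index_to_physical(idx) - c) @ axis.v
    a_pos = _slab_area(root_mask, axis.v, float(s.max()) + beyond_mm, c)
    a_neg = _slab_area(root_mask, axis.v, float(s.min()) - beyond_mm, c)
    if max(a_pos, a_neg) <= 0 or abs(a_pos - a_neg) <= 0.05 * max(a_pos, a_neg):
        if fallback_sign is None:
            raise ValueError(
                "outflow direction is ambiguous (symmetric lumen); supply an "
                "orientation flag"
            )
        return replace(axis, orientation_sign=int(fallback_sign))
    return replace(axis, orientation_sign=1 if a_pos > a_neg else -1)
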