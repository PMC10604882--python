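"""Core volumetric containers and DICOM / NIfTI I/O.

All geometry in this package lives in physical LPS millimetre coordinates
(the DICOM patient coordinate system).  A voxel index ``(i, j, k)`` maps to

    x = origin + orientation @ (spacing * (i, j, k))

with ``orientation`` a 3x3 orthonormal direction-cosine matrix.  Arrays are
stored index-ordered ``(i, j, k)`` -> ``(x-ish, y-ish, z-ish)`` axes, i.e.
the nibabel convention, and converted on the fly for SimpleITK (which wants
``(k, j, i)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk

__all__ = [
    "ScalarVolume",
    "BinaryMask",
    "Study4D",
    "read_dicom_series",
    "read_volume",
    "read_mask",
    "write_volume",
]

# RAS (nibabel/NIfTI world) <-> LPS (DICOM world): flip x and y.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0])


def _check_grid(voxels: np.ndarray, spacing, origin, orientation) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={voxels.ndim}")
    if min(voxels.shape) < 2:
        raise ValueError(f"grid dimensions must be >= 2 per axis, got {voxels.shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing}")
    orientation = np.asarray(orientation, dtype=float)
    if orientation.shape != (3, 3) or not np.allclose(
        orientation.T @ orientation, np.eye(3), atol=1e-6
    ):
        raise ValueError("orientation must be a 3x3 orthonormal matrix")


@dataclass(frozen=True)
class ScalarVolume:
    """A 3D scalar grid (Hounsfield units) with physical geometry."""

    voxels: np.ndarray
    spacing: np.ndarray  # mm, per index axis
    origin: np.ndarray = None  # mm position of voxel (0,0,0)
    orientation: np.ndarray = None  # direction cosines, columns = index axes

    def __post_init__(self):
        object.__setattr__(self, "voxels", np.asarray(self.voxels))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        origin = np.zeros(3) if self.origin is None else np.asarray(self.origin, float)
        object.__setattr__(self, "origin", origin)
        orient = np.eye(3) if self.orientation is None else np.asarray(self.orientation, float)
        object.__setattr__(self, "orientation", orient)
        _check_grid(self.voxels, self.spacing, self.origin, self.orientation)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to physical mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + (ijk * self.spacing) @ self.orientation.T

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) physical mm coordinates to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return ((xyz - self.origin) @ self.orientation) / self.spacing

    def physical_center(self) -> np.ndarray:
        """Geometric center of the grid in mm (the 'center of the study')."""
        return self.index_to_physical((np.array(self.shape, float) - 1.0) / 2.0)

    def same_grid(self, other: "ScalarVolume | BinaryMask", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.orientation, other.orientation, atol=atol)
        )

    # ---- SimpleITK bridge ------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        arr = self.voxels
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.orientation.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ScalarVolume":
        arr = sitk.GetArrayFromImage(img).T
        return cls(
            voxels=arr,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            orientation=np.array(img.GetDirection()).reshape(3, 3),
        )


@dataclass(frozen=True)
class BinaryMask(ScalarVolume):
    """A boolean segment on the exact grid of its source volume."""

    def __post_init__(self):
        object.__setattr__(self, "voxels", np.asarray(self.voxels).astype(bool))
        super().__post_init__()

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.voxel_volume

    def centroid_mm(self) -> np.ndarray:
        """Foreground center of mass (uniform voxel mass) in mm."""
        if self.count == 0:
            raise ValueError("empty mask has no centroid")
        idx = np.argwhere(self.voxels)
        return self.index_to_physical(idx.mean(axis=0))

    def with_voxels(self, voxels: np.ndarray) -> "BinaryMask":
        """New mask on the same grid."""
        return replace(self, voxels=np.asarray(voxels, dtype=bool))

    @staticmethod
    def like(volume: ScalarVolume, voxels: np.ndarray) -> "BinaryMask":
        return BinaryMask(
            voxels=np.asarray(voxels, dtype=bool),
            spacing=volume.spacing.copy(),
            origin=volume.origin.copy(),
            orientation=volume.orientation.copy(),
        )


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap coefficient between two masks on the same grid."""
    av = a.voxels if isinstance(a, BinaryMask) else np.asarray(a, bool)
    bv = b.voxels if isinstance(b, BinaryMask) else np.asarray(b, bool)
    denom = av.sum() + bv.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(av, bv).sum() / denom


@dataclass(frozen=True)
class Study4D:
    """An ordered sequence of per-phase volumes sharing one grid."""

    phases: tuple

    def __post_init__(self):
        phases = tuple(self.phases)
        if len(phases) < 1:
            raise ValueError("a 4D study needs at least one phase")
        ref = phases[0]
        for t, ph in enumerate(phases[1:], start=1):
            if not ref.same_grid(ph):
                raise ValueError(f"phase {t} is not on the grid of phase 0")
        object.__setattr__(self, "phases", phases)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def __len__(self) -> int:
        return len(self.phases)

    def __getitem__(self, t: int) -> ScalarVolume:
        return self.phases[t]

    def __iter__(self) -> Iterator[ScalarVolume]:
        return iter(self.phases)


# ---------------------------------------------------------------------------
# DICOM reading
# ---------------------------------------------------------------------------

def _slice_geometry(ds) -> tuple:
    iop = np.array(ds.ImageOrientationPatient, dtype=float)
    row, col = iop[:3], iop[3:]
    normal = np.cross(row, col)
    pos = np.array(ds.ImagePositionPatient, dtype=float)
    return row, col, normal, pos


def _phase_key(ds):
    for tag in ("TemporalPositionIdentifier", "AcquisitionNumber"):
        v = getattr(ds, tag, None)
        if v is not None:
            return int(v)
    return None


def read_dicom_series(directory: str | Path, tol: float = 1e-3) -> Study4D:
    """Read a directory of single-frame CT DICOM slices into a 4D study.

    Slices are grouped into phases by the DICOM temporal position (falling
    back to acquisition number, then to equal position-sorted blocks when a
    slice position repeats without any temporal tag), sorted within a phase
    by position along the slice normal, and rescaled to Hounsfield units.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.rglob("*") if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # non-DICOM clutter
        if not hasattr(ds, "PixelData"):
            continue
        slices.append((p, ds))
    if not slices:
        raise ValueError(f"no DICOM image slices found under {directory}")

    row, col, normal, pos0 = _slice_geometry(slices[0][1])
    recs = []
    for p, ds in slices:
        r, c, n, pos = _slice_geometry(ds)
        if not (np.allclose(r, row, atol=tol) and np.allclose(c, col, atol=tol)):
            raise ValueError(f"inconsistent slice orientation in {p}")
        z = float(np.dot(pos, normal))
        recs.append({"path": p, "ds": ds, "z": z, "phase": _phase_key(ds)})

    if all(r["phase"] is not None for r in recs):
        phase_ids = sorted({r["phase"] for r in recs})
        groups = [[r for r in recs if r["phase"] == pid] for pid in phase_ids]
    else:
        # equal-sized position-sorted blocks: n distinct z positions, each
        # repeated T times, define T phases
        recs.sort(key=lambda r: (r["z"], str(r["path"])))
        zs = np.array([r["z"] for r in recs])
        uniq = np.unique(np.round(zs / tol) * tol)
        T, rem = divmod(len(recs), len(uniq))
        if rem:
            raise ValueError(
                f"cannot group {len(recs)} slices over {len(uniq)} positions "
                "into equal phases; series is incomplete"
            )
        groups = [recs[t::T] for t in range(T)] if T > 1 else [recs]

    phases = []
    for gi, grp in enumerate(groups):
        grp = sorted(grp, key=lambda r: r["z"])
        zs = np.array([r["z"] for r in grp])
        if len(zs) < 2:
            raise ValueError(f"phase {gi} has fewer than 2 slices")
        dz = np.diff(zs)
        if np.any(dz <= 0):
            dup = grp[int(np.argmax(dz <= 0))]["path"]
            raise ValueError(f"duplicate slice position at {dup}")
        if not np.allclose(dz, dz[0], atol=0.05 * dz[0]):
            gap = int(np.argmax(np.abs(dz - np.median(dz))))
            raise ValueError(
                f"missing slice in phase {gi}: spacing jumps from "
                f"{np.median(dz):.3f} to {dz[gap]:.3f} mm after z={zs[gap]:.3f}"
            )
        planes = []
        for r in grp:
            ds = r["ds"]
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            inter = float(getattr(ds, "RescaleIntercept", 0.0))
            # pixel_array is (rows, cols); our in-plane index axes are
            # (i<->col direction, j<->row direction)
            planes.append(ds.pixel_array.T.astype(np.float32) * slope + inter)
        ds0 = grp[0]["ds"]
        ps = np.array(ds0.PixelSpacing, dtype=float)  # (row, col) mm
        spacing = np.array([ps[1], ps[0], dz[0]])
        orientation = np.column_stack([row, col, normal])
        vol = ScalarVolume(
            voxels=np.stack(planes, axis=-1),
            spacing=spacing,
            origin=np.array(grp[0]["ds"].ImagePositionPatient, dtype=float),
            orientation=orientation,
        )
        phases.append(vol)
    return Study4D(phases=tuple(phases))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_lps(vol: ScalarVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = vol.orientation @ np.diag(vol.spacing)
    aff[:3, 3] = vol.origin
    return aff


def write_volume(volume: ScalarVolume, path: str | Path) -> None:
    """Write a volume or mask to NIfTI; masks become uint8 with foreground=1."""
    aff_lps = _affine_lps(volume)
    aff_ras = np.eye(4)
    aff_ras[:3, :] = _RAS2LPS @ aff_lps[:3, :]
    data = volume.voxels
    if isinstance(volume, BinaryMask) or data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), aff_ras)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def _load_nifti(path: str | Path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    aff_ras = img.affine
    aff_lps3 = _RAS2LPS @ aff_ras[:3, :]
    M = aff_lps3[:, :3]
    spacing = np.linalg.norm(M, axis=0)
    orientation = M / spacing
    return data, spacing, aff_lps3[:, 3], orientation


def read_volume(path: str | Path) -> ScalarVolume:
    data, spacing, origin, orientation = _load_nifti(path)
    return ScalarVolume(data, spacing, origin, orientation)


def read_mask(path: str | Path) -> BinaryMask:
    data, spacing, origin, orientation = _load_nifti(path)
    return BinaryMask(data > 0, spacing, origin, orientation)
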