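"""Synthetic 4D-CT phantoms of a stented aortic valve with ground truth.

The generator emulates an ECG-gated contrast CT of a deployed
self-expanding valve prosthesis: a bright (~3000 HU) diamond-lattice
wireframe tube embedded in a contrast-filled lumen (~400 HU) on a
soft-tissue background (~40 HU), with optional speckle artifacts, a solid
calcification-like blob, a coronary-like side branch on the lumen, and
per-phase rigid translation / radial expansion of the frame.  Every
geometric quantity the analysis pipeline later measures (axis direction,
tip positions, inner volume, cross-sectional areas, masks) is returned
analytically alongside the images.

Conventions: the frame axis passes through the grid's physical center;
the outflow tip (toward the ascending aorta, h = 0) sits at the +axis end
and the lumen is extended past it, the inflow tip (annulus, h = 100%) at
the -axis end.  Normalized height h runs 0 -> 1 from outflow to inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_model import BinaryMask, ScalarVolume, Study4D

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "rasterize_wireframe"]

RadiusProfile = Callable[[np.ndarray], np.ndarray]


def _as_profile(r) -> RadiusProfile:
    if callable(r):
        return lambda h: np.asarray(r(np.asarray(h, dtype=float)), dtype=float)
    rv = float(r)
    return lambda h: np.full_like(np.asarray(h, dtype=float), rv)


def ellipsoid_struct(radius_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Anisotropy-aware ball structuring element of a physical radius."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return X**2 + Y**2 + Z**2 <= radius_mm**2 + 1e-9


@dataclass
class PhantomSpec:
    """Parameters of the synthetic study; defaults emulate a ~27 mm device
    imaged at sub-millimetre cardiac-CT resolution."""

    grid_shape: tuple = (104, 104, 100)
    spacing: tuple = (0.65, 0.65, 0.56)  # mm, typical cardiac-CT anisotropy
    frame_radius_mm: float | RadiusProfile = 10.0  # inner radius r(h)
    frame_length_mm: float = 30.0
    strut_thickness_mm: float = 1.4  # apparent (blooming-inclusive) diameter
    n_circ_cells: int = 12
    n_axial_cells: int = 8
    tilt_deg: float = 0.0
    tilt_azimuth_deg: float = 0.0
    n_phases: int = 10
    per_phase_translation_mm: Sequence | None = None  # (T,3) mm
    per_phase_radius_scale: Sequence | None = None  # (T,)
    lumen_radius_mm: float | RadiusProfile = 14.0  # R(h) > r(h)
    lumen_extension_outflow_mm: float = 15.0
    lumen_extension_inflow_mm: float = 2.0
    hu_background: float = 40.0
    hu_lumen: float = 400.0
    hu_frame: float = 3000.0
    hu_calcification: float = 1200.0
    hu_speckle: float = 1500.0
    n_speckles: int = 0
    speckle_radius_mm: tuple = (0.8, 2.0)
    calcification: dict | None = None  # {"offset_mm": (x,y,z), "radii_mm": (a,b,c)}
    branch: dict | None = None  # {"h": 0.5, "radius_mm": 2.0, "length_mm": 12.0, "azimuth_deg": 0.0}
    noise_sd: float = 20.0
    psf_sigma_mm: float = 0.15
    seed: int = 0

    def axis_direction(self) -> np.ndarray:
        """Unit frame-axis direction (outflow side positive)."""
        t = np.deg2rad(self.tilt_deg)
        a = np.deg2rad(self.tilt_azimuth_deg)
        return np.array([np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), np.cos(t)])

    def translations(self) -> np.ndarray:
        if self.per_phase_translation_mm is None:
            return np.zeros((self.n_phases, 3))
        tr = np.asarray(self.per_phase_translation_mm, dtype=float)
        if tr.shape != (self.n_phases, 3):
            raise ValueError(f"per_phase_translation_mm must be ({self.n_phases}, 3)")
        return tr

    def radius_scales(self) -> np.ndarray:
        if self.per_phase_radius_scale is None:
            return np.ones(self.n_phases)
        sc = np.asarray(self.per_phase_radius_scale, dtype=float)
        if sc.shape != (self.n_phases,):
            raise ValueError(f"per_phase_radius_scale must have length {self.n_phases}")
        return sc

    def validate(self) -> None:
        r, R = _as_profile(self.frame_radius_mm), _as_profile(self.lumen_radius_mm)
        h = np.linspace(0, 1, 201)
        if not np.all(R(h) > r(h)):
            raise ValueError("lumen radius R(h) must exceed frame radius r(h) everywhere")
        if not (self.hu_frame > self.hu_lumen > self.hu_background):
            raise ValueError("need frame HU > lumen HU > background HU")
        if self.strut_thickness_mm < max(self.spacing):
            raise ValueError(
                f"strut thickness {self.strut_thickness_mm} mm is below one voxel "
                f"(max spacing {max(self.spacing)} mm); the frame would fragment"
            )


@dataclass
class PhantomTruth:
    """Analytic ground truth of a generated phantom (arrays indexed by phase)."""

    axis_direction: np.ndarray  # (T,3) unit vectors
    tip_outflow_mm: np.ndarray  # (T,3)
    tip_inflow_mm: np.ndarray  # (T,3)
    center_of_mass_mm: np.ndarray  # (T,3) frame centroid
    inner_volume_mm3: np.ndarray  # (T,)
    frame_mask: list  # per-phase BinaryMask
    lumen_mask: list  # per-phase BinaryMask (contrast region minus struts)
    branch_mask: list = field(default_factory=list)  # per-phase BinaryMask
    h2_true_percent: float = 0.0  # location of max frame radius, % of length
    spec: PhantomSpec | None = None

    def csa_inner(self, t: int, h) -> np.ndarray:
        """pi * (r(h) * scale_t)^2 in mm^2 at normalized heights h in [0,1]."""
        r = _as_profile(self.spec.frame_radius_mm)
        s = self.spec.radius_scales()[t]
        return np.pi * (r(np.asarray(h, float)) * s) ** 2

    def csa_lumen(self, h) -> np.ndarray:
        R = _as_profile(self.spec.lumen_radius_mm)
        return np.pi * R(np.asarray(h, float)) ** 2


def rasterize_wireframe(
    curves_mm: Sequence[np.ndarray], thickness_mm: float, grid: ScalarVolume
) -> BinaryMask:
    """Rasterize polyline curves (points in mm) as tubes of the given
    diameter on the grid of ``grid``.

    A voxel is foreground when its center lies within ``thickness_mm / 2``
    of the (densely sampled) curve point cloud — an exact Euclidean test,
    so the tube surface and its center of mass are sub-voxel faithful.
    Curve points outside the grid simply contribute nothing.
    """
    fg = np.zeros(grid.shape, dtype=bool)
    pts_all = [np.asarray(p, float) for p in curves_mm if len(p)]
    if not pts_all:
        return BinaryMask.like(grid, fg)
    pts = np.concatenate(pts_all, axis=0)
    tree = cKDTree(pts)

    # candidate voxels: bounding box of the curves, padded by the tube radius
    r = thickness_mm / 2.0
    lo_idx = np.floor(grid.physical_to_index(pts.min(axis=0)) - r / grid.spacing)
    hi_idx = np.ceil(grid.physical_to_index(pts.max(axis=0)) + r / grid.spacing)
    lo = np.maximum(lo_idx.astype(int), 0)
    hi = np.minimum(hi_idx.astype(int) + 1, np.array(grid.shape))
    if np.any(lo >= hi):
        return BinaryMask.like(grid, fg)
    axes = [np.arange(a, b) for a, b in zip(lo, hi)]
    II, JJ, KK = np.meshgrid(*axes, indexing="ij")
    cand = np.stack([II.ravel(), JJ.ravel(), KK.ravel()], axis=1)
    d, _ = tree.query(grid.index_to_physical(cand), k=1, workers=-1)
    hit = cand[d <= r]
    fg[hit[:, 0], hit[:, 1], hit[:, 2]] = True
    return BinaryMask.like(grid, fg)


def _frame_curves(
    spec: PhantomSpec, center: np.ndarray, u: np.ndarray, scale: float
) -> list:
    """Strut centerline curves in mm: two helical families plus tip rings."""
    r = _as_profile(spec.frame_radius_mm)
    L = spec.frame_length_mm
    # orthonormal in-plane basis (deterministic)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    # winding chosen so the two helix families tile the surface with
    # n_axial diamond cells along the length and n_circ around
    wind = 2.0 * np.pi * spec.n_axial_cells / spec.n_circ_cells
    rbar = float(np.mean(r(np.linspace(0, 1, 64)))) * scale
    arc = np.hypot(L, rbar * wind)
    step = 0.35 * min(spec.spacing)
    n_pts = max(int(np.ceil(arc / step)), 64)
    h = np.linspace(0.0, 1.0, n_pts)
    # strut centerline sits half a strut outside the inner radius
    rc = r(h) * scale + spec.strut_thickness_mm / 2.0
    s = (0.5 - h) * L  # h=0 -> outflow at +u end

    curves = []
    for k in range(spec.n_circ_cells):
        phi0 = 2 * np.pi * k / spec.n_circ_cells
        for sgn in (+1.0, -1.0):
            phi = phi0 + sgn * wind * h
            pts = (
                center
                + np.outer(s, u)
                + np.outer(rc * np.cos(phi), e1)
                + np.outer(rc * np.sin(phi), e2)
            )
            curves.append(pts)
    # crown rings at both tips keep the frame closed and the tips sharp
    for h_tip in (0.0, 1.0):
        rt = float(r(np.array([h_tip]))[0]) * scale + spec.strut_thickness_mm / 2.0
        ang = np.linspace(0, 2 * np.pi, max(int(2 * np.pi * rt / step), 32), endpoint=False)
        pts = (
            center
            + (0.5 - h_tip) * L * u
            + np.outer(rt * np.cos(ang), e1)
            + np.outer(rt * np.sin(ang), e2)
        )
        curves.append(pts)
    return curves


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Generate a seeded, fully deterministic study and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    grid = ScalarVolume(
        voxels=np.zeros(spec.grid_shape, dtype=np.float32),
        spacing=np.asarray(spec.spacing, float),
    )
    c0 = grid.physical_center()
    u = spec.axis_direction()
    L = spec.frame_length_mm
    r_prof = _as_profile(spec.frame_radius_mm)
    R_prof = _as_profile(spec.lumen_radius_mm)

    # physical coordinates of all voxel centers, once (phases share the grid)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in spec.grid_shape), indexing="ij")
    coords = np.stack([ii, jj, kk], axis=-1) * np.asarray(spec.spacing)  # orientation=I, origin=0
    trans = spec.translations()
    scales = spec.radius_scales()

    # speckle geometry is drawn once (fixed anatomy/artifacts across phases)
    speckles = []
    for _ in range(spec.n_speckles):
        rad = rng.uniform(*spec.speckle_radius_mm)
        # keep clear of the lumen so artifact components stay isolated
        while True:
            pos = rng.uniform(8.0, np.array(spec.grid_shape) * spec.spacing - 8.0)
            rel = pos - c0
            ax = np.dot(rel, u)
            rho = np.sqrt(max(np.dot(rel, rel) - ax**2, 0.0))
            if rho > float(R_prof(np.array([0.5]))[0]) + 4.0 + rad:
                break
        speckles.append((pos, rad))

    phases, frame_masks, lumen_masks, branch_masks = [], [], [], []
    tips_out, tips_in, volumes = [], [], []
    hq = np.linspace(0.0, 1.0, 4001)
    for t in range(spec.n_phases):
        ct = c0 + trans[t]
        curves = _frame_curves(spec, ct, u, scales[t])
        frame = rasterize_wireframe(curves, spec.strut_thickness_mm, grid)
        if not frame.voxels.any():
            raise ValueError("frame rasterized to an empty mask; check spec geometry")

        rel = coords - ct
        ax = rel @ u
        rho2 = np.einsum("...i,...i", rel, rel) - ax**2
        h_vox = np.clip((L / 2.0 - ax) / L, 0.0, 1.0)
        in_lumen_span = (ax >= -L / 2.0 - spec.lumen_extension_inflow_mm) & (
            ax <= L / 2.0 + spec.lumen_extension_outflow_mm
        )
        lumen_full = in_lumen_span & (rho2 <= R_prof(h_vox) ** 2)

        branch = np.zeros(spec.grid_shape, dtype=bool)
        if spec.branch is not None:
            b = spec.branch
            hb = float(b.get("h", 0.5))
            rb = float(b.get("radius_mm", 2.0))
            lb = float(b.get("length_mm", 12.0))
            az = np.deg2rad(float(b.get("azimuth_deg", 0.0)))
            ref = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(ref, u)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(u, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            d = np.cos(az) * e1 + np.sin(az) * e2  # radial branch direction
            base = ct + (0.5 - hb) * L * u
            relb = coords - base
            along = relb @ d
            perp2 = np.einsum("...i,...i", relb, relb) - along**2
            Rb0 = float(R_prof(np.array([hb]))[0])
            branch = (along >= 0) & (along <= Rb0 + lb) & (perp2 <= rb**2)
            branch &= ~lumen_full

        # root-region truth is the full contrast tube, struts included: the
        # aortic-root cross-section spans the device (dCSA = CSAa - CSAp)
        lumen_truth = lumen_full

        vol = np.full(spec.grid_shape, spec.hu_background, dtype=np.float32)
        vol[lumen_full] = spec.hu_lumen
        vol[branch] = spec.hu_lumen
        if spec.calcification is not None:
            cc = c0 + np.asarray(spec.calcification.get("offset_mm", (24.0, 0.0, 0.0)))
            radii = np.asarray(spec.calcification.get("radii_mm", (7.0, 6.5, 6.0)))
            q = ((coords - cc) / radii) ** 2
            calc = q.sum(axis=-1) <= 1.0
            vol[calc & ~lumen_full & ~frame.voxels] = spec.hu_calcification
        for pos, rad in speckles:
            q = coords - pos
            sp = np.einsum("...i,...i", q, q) <= rad**2
            vol[sp & ~lumen_full & ~frame.voxels] = spec.hu_speckle
        vol[frame.voxels] = spec.hu_frame

        if spec.psf_sigma_mm > 0:
            vol = ndimage.gaussian_filter(vol, sigma=spec.psf_sigma_mm / np.asarray(spec.spacing))
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32)
        vol = np.clip(vol, 0.0, 4095.0).astype(np.float32)

        phases.append(ScalarVolume(vol, grid.spacing, grid.origin, grid.orientation))
        frame_masks.append(frame)
        lumen_masks.append(BinaryMask.like(grid, lumen_truth))
        branch_masks.append(BinaryMask.like(grid, branch))
        tips_out.append(ct + (L / 2.0) * u)
        tips_in.append(ct - (L / 2.0) * u)
        volumes.append(float(np.trapezoid(np.pi * (r_prof(hq) * scales[t]) ** 2, hq * L)))

    com = np.array([m.centroid_mm() for m in frame_masks])
    rq = r_prof(hq)
    truth = PhantomTruth(
        axis_direction=np.tile(u, (spec.n_phases, 1)),
        tip_outflow_mm=np.array(tips_out),
        tip_inflow_mm=np.array(tips_in),
        center_of_mass_mm=com,
        inner_volume_mm3=np.array(volumes),
        frame_mask=frame_masks,
        lumen_mask=lumen_masks,
        branch_mask=branch_masks,
        h2_true_percent=float(hq[int(np.argmax(rq))] * 100.0),
        spec=spec,
    )
    return Study4D(phases=tuple(phases)), truth
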