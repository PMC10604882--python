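"""Stent-frame segmentation: threshold, island removal, density selection.

Metal struts are far brighter than contrast-filled blood, so a single HU
threshold isolates the frame together with two artifact families: small
bright speckles and large dense anatomical structures (typically
calcifications).  Speckles fall to a minimum-size filter; dense solids are
told apart from the thread-like, hollow frame by their fill fraction —
the ratio of a component's voxel count to that of its solidified hull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frame_filling import solidify
from .image_model import BinaryMask, ScalarVolume

__all__ = [
    "SegmentationParams",
    "threshold_volume",
    "remove_small_islands",
    "component_density",
    "segment_frame",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Frame-segmentation parameters.

    ``th1``/``th2`` defaults are the published clinical operating point for
    sub-millimetre cardiac CT of nitinol devices; ``th2`` counts voxels, so
    rescale it when the voxel volume differs materially from
    0.65 x 0.65 x 0.56 mm.
    """

    th1: float = 800.0  # HU lower threshold
    th2: int = 11000  # minimum component size, voxels
    connectivity: int = 26  # 6, 18 or 26
    density_cutoff: float = 0.5  # max fill fraction of a thread-like component
    closing_radius_mm: float = 3.0  # aperture sealing for the solidified hull

    def __post_init__(self):
        if not (0.0 < self.th1 < 4095.0):
            raise ValueError("th1 must lie in (0, 4095) HU")
        if self.th2 < 1:
            raise ValueError("th2 must be >= 1 voxel")
        if not (0.0 < self.density_cutoff < 1.0):
            raise ValueError("density_cutoff must lie in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def threshold_volume(volume: ScalarVolume, th1: float) -> BinaryMask:
    """Select all voxels strictly brighter than ``th1`` HU."""
    fg = volume.voxels > th1
    if not fg.any():
        raise ValueError(
            f"no candidate prosthesis voxels: nothing exceeds {th1} HU"
        )
    return BinaryMask.like(volume, fg)


def remove_small_islands(mask: BinaryMask, th2: int, connectivity: int = 26) -> BinaryMask:
    """Drop connected components smaller than ``th2`` voxels (>= th2 kept)."""
    lab, n = ndimage.label(mask.voxels, structure=_structure(connectivity))
    if n == 0:
        raise ValueError("mask is empty")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= th2) + 1
    if keep.size == 0:
        raise ValueError(
            f"all {n} components are smaller than th2={th2} voxels; "
            "th2 is too large for this study"
        )
    return mask.with_voxels(np.isin(lab, keep))


def component_density(component: BinaryMask, closing_radius_mm: float = 3.0) -> float:
    """Fill fraction of a single connected component in (0, 1].

    The solidified hull is the component after sealing surface apertures
    (morphological closing with a ball of ``closing_radius_mm``), capping
    open tube mouths, and filling every internal cavity; a solid blob
    scores ~1, a hollow shell or a wireframe tube scores low.
    """
    if not component.voxels.any():
        raise ValueError("empty component")
    solid, _, caps = solidify(component, closing_radius_mm)
    # the synthetic mouth caps are scaffolding, not structure: they stay out
    # of the hull volume
    hull = (solid & ~caps) | component.voxels
    return float(component.voxels.sum() / hull.sum())


def segment_frame(volume: ScalarVolume,
                  params: SegmentationParams = SegmentationParams()) -> BinaryMask:
    """Threshold, remove speckles, and keep the least-dense (thread-like)
    component: the prosthesis frame.  Returns a single connected component."""
    mask = remove_small_islands(
        threshold_volume(volume, params.th1), params.th2, params.connectivity
    )
    lab, n = ndimage.label(mask.voxels, structure=_structure(params.connectivity))
    densities = []
    for i in range(1, n + 1):
        comp = mask.with_voxels(lab == i)
        densities.append(component_density(comp, params.closing_radius_mm))
    order = int(np.argmin(densities))
    if densities[order] > params.density_cutoff:
        raise ValueError(
            "no thread-like structure found: minimum component fill fraction "
            f"{densities[order]:.2f} exceeds the cutoff {params.density_cutoff}"
        )
    return mask.with_voxels(lab == order + 1)
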