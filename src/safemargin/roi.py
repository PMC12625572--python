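"""Tumor refinement and region-of-interest cropping.

Only the part of the tumor that lies inside bone can seed intraosseous margin
growth; tumor annotated outside the bone surface does not contact bone and
must not inflate the resection.  The refined tumor is therefore the voxelwise
intersection of the tumor and bone masks, and all downstream computation runs
on a cuboid ROI: the refined tumor's bounding box grown by the safe margin
``d_s`` plus a slack ``xi`` that absorbs discretization effects.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import DomainError, EmptyMaskError, EmptyRefinedTumorError
from .grid import (
    IndexBox,
    MaskVolume,
    PhysicalBox,
    mm_box_to_index_box,
    require_same_grid,
)

__all__ = ["refine_tumor", "tumor_bbox", "expand_bbox", "crop_pair", "DEFAULT_XI_MM"]

logger = logging.getLogger(__name__)

#: Default ROI slack beyond the safe margin, mm.  Exceeds any discretization
#: slack at clinical spacings (<= 1 mm voxels).
DEFAULT_XI_MM = 2.0


def refine_tumor(bone: MaskVolume, tumor: MaskVolume) -> MaskVolume:
    """Voxelwise intersection of tumor with bone on their shared grid.

    Raises :class:`EmptyRefinedTumorError` when the masks do not intersect
    (there is no intraosseous tumor to protect) and
    :class:`IncompatibleGridsError` when the grids differ.
    """
    require_same_grid(bone, tumor, "bone and tumor masks")
    refined = bone.occupancy & tumor.occupancy
    if not refined.any():
        raise EmptyRefinedTumorError(
            "bone and tumor masks do not intersect; no intraosseous tumor"
        )
    return bone.with_occupancy(refined)


def tumor_bbox(tumor: MaskVolume) -> PhysicalBox:
    """Bounding box (mm) of the true-voxel centers of the refined tumor."""
    occ = tumor.occupancy
    if not occ.any():
        raise EmptyMaskError("cannot take the bounding box of an empty mask")
    ii, jj, kk = np.nonzero(occ)
    return PhysicalBox(
        (
            tumor.origin_x + ii.min() * tumor.spacing_x,
            tumor.origin_y + jj.min() * tumor.spacing_y,
            float(tumor.slice_z[kk.min()]),
        ),
        (
            tumor.origin_x + ii.max() * tumor.spacing_x,
            tumor.origin_y + jj.max() * tumor.spacing_y,
            float(tumor.slice_z[kk.max()]),
        ),
    )


def expand_bbox(b_t: PhysicalBox, d_s: float, xi: float = DEFAULT_XI_MM) -> PhysicalBox:
    """Grow the tumor bounding box by ``d_s + xi`` mm on every face."""
    if d_s < 0:
        raise DomainError("safe margin must be non-negative")
    if xi <= 0:
        raise DomainError("ROI slack xi must be positive")
    return b_t.expand(d_s + xi)


def crop_pair(
    bone: MaskVolume, tumor: MaskVolume, b_roi: PhysicalBox
) -> tuple[MaskVolume, MaskVolume]:
    """Crop bone and tumor to the same index box covering ``b_roi``.

    The returned volumes keep the physical position of every surviving voxel:
    the origin and the slice-z table are shifted/sliced accordingly.  A box
    reaching past the scan extent is clamped with a warning -- clinically the
    margin may simply be truncated by the field of view.
    """
    require_same_grid(bone, tumor, "bone and tumor masks")
    idx = mm_box_to_index_box(bone, b_roi)
    if _box_exceeds_extent(b_roi, bone.physical_extent()):
        logger.warning(
            "ROI box %s..%s exceeds the scan extent; cropping is clamped and the "
            "margin may be truncated",
            b_roi.min_corner,
            b_roi.max_corner,
        )
    return _crop(bone, idx), _crop(tumor, idx)


def _box_exceeds_extent(box: PhysicalBox, extent: PhysicalBox) -> bool:
    return any(a < b for a, b in zip(box.min_corner, extent.min_corner)) or any(
        a > b for a, b in zip(box.max_corner, extent.max_corner)
    )


def _crop(vol: MaskVolume, idx: IndexBox) -> MaskVolume:
    sl = idx.slices
    return MaskVolume(
        occupancy=vol.occupancy[sl].copy(),
        spacing_x=vol.spacing_x,
        spacing_y=vol.spacing_y,
        slice_z=vol.slice_z[sl[2]].copy(),
        origin_x=vol.origin_x + idx.lo[0] * vol.spacing_x,
        origin_y=vol.origin_y + idx.lo[1] * vol.spacing_y,
    )
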