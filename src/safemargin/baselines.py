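"""Comparison methods and the brute-force point-based oracle.

``pointwise_oracle`` is the predecessor point-cloud method: convert both
masks to voxel-center point sets and keep every bone point within ``d_s`` of
some refined-tumor point, by explicit nearest-neighbour search.  It shares no
code with the distance-transform path and serves as the independence check:
the coarse distance-transform volume must reproduce its point set exactly.

``dilation_baseline`` deliberately reproduces the weakness of voxel-unit
morphological dilation: a spherical structuring element of radius
``round(d_s / S_x)`` voxels is isotropic in *index* space, so on anisotropic
grids the expansion is wrong in physical millimetres.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import MaskVolume, grid_to_points
from .margin import anisotropic_distance_map, clip_to_bone, threshold_margin
from .resample import mean_slice_spacing
from .roi import refine_tumor

__all__ = ["pointwise_oracle", "coarse_only_method", "dilation_baseline"]


def pointwise_oracle(bone: MaskVolume, tumor: MaskVolume, d_s: float) -> np.ndarray:
    """Bone voxel centers within ``d_s`` mm of the refined tumor, by search.

    Point-domain brute force (KD-tree accelerated, which does not change the
    result); no distance transform involved.  Returns an ``(N, 3)`` array in
    the deterministic ordering of :func:`grid_to_points`.
    """
    refined = refine_tumor(bone, tumor)
    p_int = grid_to_points(refined)
    p_b = grid_to_points(bone)
    if p_b.size == 0:
        return p_b
    dist, _ = cKDTree(p_int).query(p_b)
    return p_b[dist <= d_s]


def coarse_only_method(bone: MaskVolume, tumor: MaskVolume, d_s: float) -> MaskVolume:
    """Distance-transform margin volume on the original grid, no resampling.

    Spacings are ``(S_x, S_y, D_bar)`` with ``D_bar`` the mean inter-slice
    gap; accuracy is limited to roughly the largest original spacing.
    """
    refined = refine_tumor(bone, tumor)
    spacings = (bone.spacing_x, bone.spacing_y, mean_slice_spacing(bone.slice_z))
    dist = anisotropic_distance_map(refined, spacings)
    return clip_to_bone(threshold_margin(dist, d_s), bone)


def ball_offsets(radius_vox: int) -> np.ndarray:
    """Discrete ball structuring element: offsets with ``|d|^2 <= r^2``."""
    r = int(radius_vox)
    if r < 0:
        raise ValueError("radius must be non-negative")
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (dx * dx + dy * dy + dz * dz) <= r * r


def dilation_baseline(bone: MaskVolume, tumor: MaskVolume, d_s: float) -> MaskVolume:
    """Morphological dilation of the refined tumor, clipped to bone.

    The ball radius is ``round(d_s / S_x)`` voxels on every axis, ignoring
    anisotropy -- the behavior this baseline is meant to exhibit.
    """
    refined = refine_tumor(bone, tumor)
    r_vox = int(round(d_s / bone.spacing_x))
    if r_vox == 0:
        dilated = refined.occupancy.copy()
    else:
        dilated = ndimage.binary_dilation(
            refined.occupancy, structure=ball_offsets(r_vox)
        )
    return clip_to_bone(bone.with_occupancy(dilated), bone)
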