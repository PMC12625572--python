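"""Anisotropic distance transform and coarse+ring safe-margin generation.

The safe-margin volume is the tumor plus all bone within the safe margin
``d_s`` (mm) of it.  It is built in two resolutions and fused:

* **coarse path** -- exact Euclidean distance transform of the refined tumor
  on the original cropped grid, using the physical spacings
  ``(S_x, S_y, D_bar)``; thresholding at ``d_s`` (inclusive) and clipping to
  bone gives the coarse volume ``V_d``, which carries the bulk structure at
  original resolution.
* **fine path** -- both ROIs are replication-resampled to ~``S_t`` spacing,
  the distance transform is recomputed on the fine grid, and only the thin
  *dangerous ring* with distances in ``[d_s - 2*max(S_hat), d_s]`` is kept
  (again clipped to bone).  The ring contributes the sub-voxel-accurate outer
  surface without the cost of storing the full fine volume.

The fused point set is the union of the coarse-volume and ring voxel centers.
Because the distance transform is exact (not chamfer) and 1-Lipschitz with
respect to physical distance, every outer-boundary ring voxel sits within
``max(S_hat)`` of the true ``d_s`` offset surface -- the source of the
~0.1 mm accuracy of the method.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

from .errors import (
    DomainError,
    EmptyForegroundError,
    ReconstructionError,
)
from .grid import MaskVolume, grid_to_points, require_same_grid
from .resample import (
    DEFAULT_TARGET_SPACING_MM,
    mean_slice_spacing,
    resample_grid,
    resampled_geometry,
    resampling_coefficients,
)
from .roi import DEFAULT_XI_MM, crop_pair, expand_bbox, refine_tumor, tumor_bbox

__all__ = [
    "DistanceMap",
    "SafeMarginResult",
    "anisotropic_distance_map",
    "threshold_margin",
    "clip_to_bone",
    "extract_ring",
    "generate_safe_margin_volume",
    "reconstruct_surface",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMap:
    """Minimum Euclidean distance (mm) to a foreground set, per voxel.

    ``values`` shares the shape and geometry of the source grid; ``spacings``
    are the scalar per-axis spacings the metric used (along z this is the
    nominal fine/mean spacing even when the slice table is non-uniform).
    """

    values: np.ndarray
    grid: MaskVolume
    spacings: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise DomainError("distance values do not match the grid shape")
        self.spacings = tuple(float(s) for s in self.spacings)


@dataclass
class SafeMarginResult:
    """Output of the coarse+ring fusion pipeline.

    ``fused_points`` is the final point set (union of coarse-volume and ring
    voxel centers, mm).  The fine-grid intermediates are kept by default so
    the geometric-error evaluation can reuse them; pass
    ``keep_intermediates=False`` to drop them and save ~0.5 GB on clinical
    ROIs.
    """

    coarse_mask: MaskVolume
    ring_mask: MaskVolume
    fused_points: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)
    coarse_distance: DistanceMap | None = None
    fine_distance: DistanceMap | None = None
    fine_bone: MaskVolume | None = None
    fine_tumor: MaskVolume | None = None
    timings: dict[str, float] = field(default_factory=dict)


def anisotropic_distance_map(
    fg: MaskVolume, spacings: tuple[float, float, float]
) -> DistanceMap:
    """Exact Euclidean distance (mm) of every voxel to the foreground set.

    The metric weights index offsets by the per-axis spacings:
    ``sqrt((S_x d_x)^2 + (S_y d_y)^2 + (S_z d_z)^2)``.  Computed with the
    exact separable transform; foreground voxels get distance zero.
    """
    if not fg.occupancy.any():
        raise EmptyForegroundError("distance transform needs a non-empty foreground")
    sp = tuple(float(s) for s in spacings)
    if len(sp) != 3 or min(sp) <= 0:
        raise DomainError("spacings must be three positive values")
    values = ndimage.distance_transform_edt(~fg.occupancy, sampling=sp)
    return DistanceMap(values=values, grid=fg, spacings=sp)


def threshold_margin(distance: DistanceMap, d_s: float) -> MaskVolume:
    """Voxels within the safe margin: ``D <= d_s`` (inclusive)."""
    if d_s < 0:
        raise DomainError("safe margin must be non-negative")
    return distance.grid.with_occupancy(distance.values <= d_s)


def clip_to_bone(margin: MaskVolume, bone: MaskVolume) -> MaskVolume:
    """Restrict the margin volume to bone: the margin grows along bone only."""
    require_same_grid(margin, bone, "margin and bone masks")
    return margin.with_occupancy(margin.occupancy & bone.occupancy)


def ring_band_width(spacings: tuple[float, float, float]) -> float:
    """Width of the dangerous ring band: twice the largest fine spacing."""
    return 2.0 * max(float(s) for s in spacings)


def extract_ring(
    distance: DistanceMap,
    d_s: float,
    spacings: tuple[float, float, float] | None = None,
) -> MaskVolume:
    """Dangerous ring: ``d_s - 2*max(S_hat) <= D <= d_s`` (both inclusive)."""
    sp = distance.spacings if spacings is None else tuple(map(float, spacings))
    band = ring_band_width(sp)
    if d_s - band <= 0:
        raise DomainError(
            f"safe margin {d_s} mm must exceed the ring band width {band:.4f} mm"
        )
    occ = (distance.values >= d_s - band) & (distance.values <= d_s)
    return distance.grid.with_occupancy(occ)


def generate_safe_margin_volume(
    bone: MaskVolume,
    tumor: MaskVolume,
    d_s: float,
    s_t: float = DEFAULT_TARGET_SPACING_MM,
    xi: float = DEFAULT_XI_MM,
    dedupe: bool = False,
    keep_intermediates: bool = True,
) -> SafeMarginResult:
    """Run the full coarse+ring pipeline on co-registered bone/tumor masks.

    Steps: refine tumor by bone intersection; crop both masks to the tumor
    bounding box grown by ``d_s + xi``; coarse distance transform, threshold,
    bone clip; replication-resample both ROIs to ``s_t``; fine distance
    transform, ring extraction, bone clip; fuse the two point sets.

    ``dedupe`` drops exact duplicate points where the ring and coarse sets
    coincide (off by default; duplicates are harmless for Delaunay export).
    """
    if d_s <= 0:
        raise DomainError("safe margin must be positive")
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    refined = refine_tumor(bone, tumor)
    b_roi = expand_bbox(tumor_bbox(refined), d_s, xi)
    bone_c, tumor_c = crop_pair(bone, refined, b_roi)
    timings["roi"] = time.perf_counter() - t0

    # coarse path on the original cropped grid
    t0 = time.perf_counter()
    d_bar = mean_slice_spacing(bone_c.slice_z)
    coarse_sp = (bone_c.spacing_x, bone_c.spacing_y, d_bar)
    coarse_dist = anisotropic_distance_map(tumor_c, coarse_sp)
    coarse_mask = clip_to_bone(threshold_margin(coarse_dist, d_s), bone_c)
    timings["coarse"] = time.perf_counter() - t0

    # fine path on the replicated grid
    t0 = time.perf_counter()
    plan = resampling_coefficients(bone_c.spacing_x, bone_c.spacing_y, d_bar, s_t)
    geom = resampled_geometry(bone_c, plan)
    fine_sp = (geom.spacing_x, geom.spacing_y, geom.spacing_z)
    bone_f = resample_grid(bone_c, s_t, plan=plan)
    tumor_f = resample_grid(tumor_c, s_t, plan=plan)
    timings["resample"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fine_dist = anisotropic_distance_map(tumor_f, fine_sp)
    ring_mask = clip_to_bone(extract_ring(fine_dist, d_s, fine_sp), bone_f)
    timings["fine"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fused = np.vstack([grid_to_points(coarse_mask), grid_to_points(ring_mask)])
    if dedupe and fused.size:
        fused = np.unique(fused, axis=0)
    timings["fuse"] = time.perf_counter() - t0
    logger.info(
        "safe-margin volume: %d coarse + %d ring voxels (%s)",
        coarse_mask.n_true,
        ring_mask.n_true,
        ", ".join(f"{k}={v:.2f}s" for k, v in timings.items()),
    )

    result = SafeMarginResult(
        coarse_mask=coarse_mask,
        ring_mask=ring_mask,
        fused_points=fused,
        params={
            "d_s_mm": float(d_s),
            "target_spacing_mm": float(s_t),
            "xi_mm": float(xi),
            "band_width_mm": ring_band_width(fine_sp),
            "replication_factors": plan.factors,
            "fine_spacings_mm": fine_sp,
            "coarse_spacings_mm": coarse_sp,
            "dedupe": bool(dedupe),
        },
        timings=timings,
    )
    if keep_intermediates:
        result.coarse_distance = coarse_dist
        result.fine_distance = fine_dist
        result.fine_bone = bone_f
        result.fine_tumor = tumor_f
    return result


def reconstruct_surface(points: np.ndarray):
    """Boundary surface of the Delaunay tetrahedralization of a point set.

    Returns a ``trimesh.Trimesh`` whose faces are the tetrahedral-complex
    boundary triangles (the convex hull for a full Delaunay complex);
    watertight for convex inputs.  Raises :class:`ReconstructionError` for
    fewer than four points or degenerate (coplanar) input.
    """
    import trimesh

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ReconstructionError("need at least four 3D points")
    try:
        tet = Delaunay(pts)
    except QhullError as exc:
        raise ReconstructionError(f"degenerate point set: {exc}") from exc
    # boundary triangles = faces belonging to exactly one tetrahedron
    faces = np.vstack(
        [tet.simplices[:, cols] for cols in ((1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2))]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inv] == 1]
    mesh = trimesh.Trimesh(vertices=pts, faces=boundary, process=True)
    trimesh.repair.fix_normals(mesh)
    return mesh
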