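"""Synthetic bone/tumor phantoms with analytic ground truth.

A phantom is a spherical (or ellipsoidal) tumor embedded centrally in a
cuboid block of bone, digitized on an anisotropic grid with clinically
realistic spacings (default 0.75 x 0.75 x 0.80 mm).  Because the tumor has a
closed-form descriptor, the distance from any point to the continuous tumor
surface is known exactly, and the margin-generation bounds can be checked
without clinical data.  Generation is fully deterministic given the
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError
from .grid import MaskVolume
from .resample import mean_slice_spacing

__all__ = [
    "SphereDescriptor",
    "Phantom",
    "make_sphere_phantom",
    "make_ellipsoid_phantom",
    "make_nonuniform_z_phantom",
    "analytic_distance",
    "DEFAULT_SPACING_MM",
    "DEFAULT_BONE_HALF_WIDTHS_MM",
    "DEFAULT_TUMOR_RADIUS_MM",
    "DEFAULT_SAFE_MARGIN_MM",
]

#: Clinically typical anisotropic spacings (mm).
DEFAULT_SPACING_MM = (0.75, 0.75, 0.80)
DEFAULT_BONE_HALF_WIDTHS_MM = (16.0, 16.0, 16.0)
DEFAULT_TUMOR_RADIUS_MM = 4.0
DEFAULT_SAFE_MARGIN_MM = 10.0


@dataclass(frozen=True)
class SphereDescriptor:
    """Analytic tumor descriptor: ball of ``radius`` at ``center`` (mm).

    ``radii`` is set instead of ``radius`` for the ellipsoid variant, which
    has no closed-form surface distance and is used for robustness tests only.
    """

    center: tuple[float, float, float]
    radius: float | None
    bone_half_widths: tuple[float, float, float]
    radii: tuple[float, float, float] | None = None


@dataclass
class Phantom:
    bone: MaskVolume
    tumor: MaskVolume
    descriptor: SphereDescriptor
    seed: int | None = None


def _symmetric_grid(center: float, half_width: float, spacing: float,
                    pad_voxels: int = 1) -> tuple[int, float]:
    """Number of voxels per side and origin for a grid centered on ``center``."""
    n_side = int(np.ceil(half_width / spacing)) + pad_voxels
    return 2 * n_side + 1, center - n_side * spacing


def _build_masks(
    spacing: tuple[float, float, float],
    bone_half_widths: tuple[float, float, float],
    center: tuple[float, float, float],
    tumor_fn,
) -> tuple[MaskVolume, MaskVolume]:
    s_x, s_y, s_z = (float(s) for s in spacing)
    hx, ox = _symmetric_grid(center[0], bone_half_widths[0], s_x)
    hy, oy = _symmetric_grid(center[1], bone_half_widths[1], s_y)
    hz, oz = _symmetric_grid(center[2], bone_half_widths[2], s_z)
    x = ox + s_x * np.arange(hx)
    y = oy + s_y * np.arange(hy)
    z = oz + s_z * np.arange(hz)
    xx = x[:, None, None]
    yy = y[None, :, None]
    zz = z[None, None, :]
    bone_occ = (
        (np.abs(xx - center[0]) <= bone_half_widths[0])
        & (np.abs(yy - center[1]) <= bone_half_widths[1])
        & (np.abs(zz - center[2]) <= bone_half_widths[2])
    )
    tumor_occ = tumor_fn(xx, yy, zz)
    bone = MaskVolume(bone_occ, s_x, s_y, z, ox, oy)
    return bone, bone.with_occupancy(tumor_occ)


def make_sphere_phantom(
    spacing: tuple[float, float, float] = DEFAULT_SPACING_MM,
    bone_half_widths: tuple[float, float, float] = DEFAULT_BONE_HALF_WIDTHS_MM,
    radius: float = DEFAULT_TUMOR_RADIUS_MM,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    d_s_max: float = DEFAULT_SAFE_MARGIN_MM,
) -> Phantom:
    """Spherical tumor of ``radius`` mm centered in a cuboid bone block.

    A voxel is tumor when its center lies within ``radius`` of ``center`` and
    bone when it lies inside the half-width box.  The box must leave room for
    the largest intended margin: ``min(half_widths) > radius + d_s_max +
    max(spacing)``, so the margin boundary never touches the bone faces.
    """
    spacing = tuple(float(s) for s in spacing)
    bone_half_widths = tuple(float(w) for w in bone_half_widths)
    center = tuple(float(c) for c in center)
    if radius <= 2 * max(spacing):
        raise DomainError("tumor radius must exceed twice the largest spacing")
    if min(bone_half_widths) < radius + d_s_max + max(spacing):
        raise DomainError(
            "bone box too small: needs half-widths >= tumor radius + margin + "
            "one voxel so the margin boundary stays inside bone"
        )

    def tumor_fn(xx, yy, zz):
        r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
        return r2 <= radius * radius

    bone, tumor = _build_masks(spacing, bone_half_widths, center, tumor_fn)
    return Phantom(
        bone=bone,
        tumor=tumor,
        descriptor=SphereDescriptor(center, float(radius), bone_half_widths),
    )


def make_ellipsoid_phantom(
    spacing: tuple[float, float, float] = DEFAULT_SPACING_MM,
    bone_half_widths: tuple[float, float, float] = DEFAULT_BONE_HALF_WIDTHS_MM,
    radii: tuple[float, float, float] = (5.0, 4.0, 3.0),
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    d_s_max: float = DEFAULT_SAFE_MARGIN_MM,
) -> Phantom:
    """Ellipsoidal-tumor variant for robustness tests (no analytic distance)."""
    spacing = tuple(float(s) for s in spacing)
    bone_half_widths = tuple(float(w) for w in bone_half_widths)
    center = tuple(float(c) for c in center)
    radii = tuple(float(r) for r in radii)
    if min(radii) <= max(spacing):
        raise DomainError("ellipsoid radii must exceed the largest spacing")
    if min(bone_half_widths) < max(radii) + d_s_max + max(spacing):
        raise DomainError("bone box too small for the requested margin")

    def tumor_fn(xx, yy, zz):
        q = (
            ((xx - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2
            + ((zz - center[2]) / radii[2]) ** 2
        )
        return q <= 1.0

    bone, tumor = _build_masks(spacing, bone_half_widths, center, tumor_fn)
    return Phantom(
        bone=bone,
        tumor=tumor,
        descriptor=SphereDescriptor(center, None, bone_half_widths, radii=radii),
    )


def make_nonuniform_z_phantom(
    base: Phantom, jitter_fraction: float, seed: int
) -> Phantom:
    """Perturb interior slice z positions by seeded uniform jitter.

    Each interior slice moves by up to ``jitter_fraction`` of the mean gap;
    the perturbation is halved until strict ordering is preserved (always
    terminates for ``jitter_fraction < 0.3``).  The mean gap, hence the
    resampling plan, is unchanged because the endpoints stay fixed.
    """
    if not 0 <= jitter_fraction < 0.3:
        raise DomainError("jitter fraction must be in [0, 0.3)")
    z = base.bone.slice_z.copy()
    if jitter_fraction == 0 or z.size < 3:
        return replace(base, seed=seed)
    d_bar = mean_slice_spacing(z)
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-1.0, 1.0, size=z.size - 2) * jitter_fraction * d_bar
    new_z = z.copy()
    while True:
        new_z[1:-1] = z[1:-1] + jitter
        if np.all(np.diff(new_z) > 0):
            break
        jitter *= 0.5
    bone = MaskVolume(base.bone.occupancy, base.bone.spacing_x,
                      base.bone.spacing_y, new_z,
                      base.bone.origin_x, base.bone.origin_y)
    return Phantom(
        bone=bone,
        tumor=bone.with_occupancy(base.tumor.occupancy),
        descriptor=base.descriptor,
        seed=seed,
    )


def analytic_distance(p, phantom: Phantom) -> float:
    """Exact distance (mm) from a point to the continuous tumor surface.

    ``max(0, |p - c| - r)`` for the sphere descriptor; zero inside the tumor.
    Useful for coarse sanity checks at half-voxel-diagonal tolerance (the
    digitization gap between the continuous ball and its voxelization); the
    primary evaluation reference remains the voxel-center set.
    """
    desc = phantom.descriptor
    if desc.radius is None:
        raise DomainError("analytic distance requires a sphere descriptor")
    p = np.asarray(p, dtype=float)
    return float(max(0.0, np.linalg.norm(p - np.asarray(desc.center)) - desc.radius))
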