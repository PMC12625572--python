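"""Odd-integer replication resampling of binary ROIs.

The fine-grid stage needs voxel spacings near a target ``S_t`` (0.10 mm by
default).  Each coarse voxel is replicated ``C`` times per axis with ``C`` the
smallest positive *odd* integer for which the resulting spacing does not
exceed ``S_t``:

    C = 2 * ceil((S / S_t + 1) / 2) - 1

Oddness keeps the block of sub-voxel centers symmetric about the parent
center in-plane, so the resampled grid is a strict refinement of the coarse
one.  Replication runs in two stages (in-plane first, then z) to bound peak
memory; it is pure block replication -- nearest-neighbour semantics with no
smoothing -- so mask content is preserved exactly.

Along z the stack may be non-uniform, so the plan is computed from the mean
inter-slice gap ``D_bar = (P_z^n - P_z^1) / (n - 1)`` and the recomputed fine
spacing is ``S_hat_z = (P_z^n - P_z^1) / (n * C_z - 1)``.  Fine slice
positions are assigned by piecewise-linear interpolation of the original
slice-position table at the fractional index ``u = j * (n - 1) / (n*C_z - 1)``:
both stack endpoints are preserved, a uniform stack resamples to an exactly
uniform stack with step ``S_hat_z``, and local gap variations are followed
proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateStackError, DomainError
from .grid import MaskVolume

__all__ = [
    "ResamplePlan",
    "ResampledGeometry",
    "mean_slice_spacing",
    "resampling_coefficients",
    "replicate_mask",
    "resampled_geometry",
    "resample_grid",
    "DEFAULT_TARGET_SPACING_MM",
]

DEFAULT_TARGET_SPACING_MM = 0.10


@dataclass(frozen=True)
class ResamplePlan:
    """Replication factors and the spacings they were derived from."""

    c_x: int
    c_y: int
    c_z: int
    k_1: int
    k_2: int
    k_3: int
    target_spacing: float
    spacing_x: float
    spacing_y: float
    mean_z_spacing: float

    def __post_init__(self) -> None:
        for name, c, k in (("x", self.c_x, self.k_1), ("y", self.c_y, self.k_2),
                           ("z", self.c_z, self.k_3)):
            if k < 1 or c != 2 * k - 1:
                raise DomainError(f"C_{name}={c} is not 2*k-1 for k={k} >= 1")

    @property
    def factors(self) -> tuple[int, int, int]:
        return (self.c_x, self.c_y, self.c_z)


class ResampledGeometry(NamedTuple):
    """Recomputed geometry of a replicated grid."""

    spacing_x: float
    spacing_y: float
    spacing_z: float
    origin_x: float
    origin_y: float
    slice_z: np.ndarray


def mean_slice_spacing(slice_z) -> float:
    """Average inter-slice gap ``(P_z^n - P_z^1) / (n - 1)`` in mm."""
    z = np.asarray(slice_z, dtype=float).ravel()
    if z.size < 2:
        raise DegenerateStackError("need at least two slices for a z spacing")
    return float(z[-1] - z[0]) / (z.size - 1)


def _odd_coefficient(spacing: float, target: float) -> tuple[int, int]:
    k = math.ceil((spacing / target + 1.0) / 2.0)
    return 2 * k - 1, k


def resampling_coefficients(
    s_x: float, s_y: float, d_bar: float, s_t: float
) -> ResamplePlan:
    """Smallest odd replication factors bringing every spacing to ``<= s_t``."""
    if min(s_x, s_y, d_bar, s_t) <= 0:
        raise DomainError("spacings and target spacing must be positive")
    c_x, k_1 = _odd_coefficient(s_x, s_t)
    c_y, k_2 = _odd_coefficient(s_y, s_t)
    c_z, k_3 = _odd_coefficient(d_bar, s_t)
    return ResamplePlan(
        c_x=c_x, c_y=c_y, c_z=c_z, k_1=k_1, k_2=k_2, k_3=k_3,
        target_spacing=float(s_t), spacing_x=float(s_x), spacing_y=float(s_y),
        mean_z_spacing=float(d_bar),
    )


def _check_factor(c: int, axis: str) -> None:
    if c < 1 or c % 2 == 0:
        raise DomainError(f"replication factor along {axis} must be odd and >= 1, got {c}")


def replicate_mask(mask: np.ndarray, c_x: int, c_y: int, c_z: int) -> np.ndarray:
    """Block-replicate a boolean lattice ``(c_x, c_y, c_z)`` times per axis.

    Two-stage: both in-plane axes first, then z, so the peak intermediate is
    ``c_x * c_y`` times the input rather than ``c_x * c_y * c_z``.
    """
    for c, axis in ((c_x, "x"), (c_y, "y"), (c_z, "z")):
        _check_factor(c, axis)
    arr = np.asarray(mask)
    if arr.ndim != 3:
        raise DomainError("mask must be 3D")
    inplane = arr.repeat(c_x, axis=0).repeat(c_y, axis=1)
    return inplane.repeat(c_z, axis=2)


def resampled_geometry(grid: MaskVolume, plan: ResamplePlan) -> ResampledGeometry:
    """Spacings, origin and slice positions of the replicated grid."""
    hz = grid.shape[2]
    if hz < 2:
        raise DegenerateStackError("need at least two slices to resample in z")
    s_hat_x = grid.spacing_x / plan.c_x
    s_hat_y = grid.spacing_y / plan.c_y
    n_fine = hz * plan.c_z
    z = grid.slice_z
    s_hat_z = float(z[-1] - z[0]) / (n_fine - 1)
    origin_x = grid.origin_x + (-plan.c_x / 2.0 + 0.5) * s_hat_x
    origin_y = grid.origin_y + (-plan.c_y / 2.0 + 0.5) * s_hat_y
    u = np.arange(n_fine) * (hz - 1) / (n_fine - 1)
    fine_z = np.interp(u, np.arange(hz), z)
    return ResampledGeometry(s_hat_x, s_hat_y, s_hat_z, origin_x, origin_y, fine_z)


def resample_grid(
    grid: MaskVolume,
    s_t: float = DEFAULT_TARGET_SPACING_MM,
    plan: ResamplePlan | None = None,
) -> MaskVolume:
    """Replicate a mask volume so every spacing is at most ``s_t``.

    A precomputed ``plan`` may be supplied (e.g. shared between the bone and
    tumor ROIs); otherwise it is derived from the grid's own spacings.
    """
    if plan is None:
        plan = resampling_coefficients(
            grid.spacing_x, grid.spacing_y, mean_slice_spacing(grid.slice_z), s_t
        )
    geom = resampled_geometry(grid, plan)
    occ = replicate_mask(grid.occupancy, *plan.factors)
    return MaskVolume(
        occupancy=occ,
        spacing_x=geom.spacing_x,
        spacing_y=geom.spacing_y,
        slice_z=geom.slice_z,
        origin_x=geom.origin_x,
        origin_y=geom.origin_y,
    )
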