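"""Exception hierarchy shared across the package."""


class SafeMarginError(Exception):
    """Base class for all package-specific errors."""


class IncompatibleGridsError(SafeMarginError):
    """Two volumes that must share a grid (shape, spacing, origin, z) do not."""


class EmptyMaskError(SafeMarginError):
    """An operation that requires at least one foreground voxel got none."""


class EmptyRefinedTumorError(EmptyMaskError):
    """Bone and tumor masks do not intersect: nothing to protect."""


class EmptySelectionError(SafeMarginError):
    """A crop or boundary selection produced no voxels."""


class EmptyForegroundError(EmptyMaskError):
    """Distance transform requested with an empty foreground set."""


class DegenerateStackError(SafeMarginError):
    """Fewer than two slices: no slice spacing can be defined."""


class DomainError(SafeMarginError):
    """A numeric parameter is outside its valid domain."""


class ReconstructionError(SafeMarginError):
    """Surface reconstruction failed (too few or degenerate points)."""


class EvaluationError(SafeMarginError):
    """Geometric-error evaluation could not select any boundary points."""


class FormatError(SafeMarginError):
    """An input file is not a usable binary mask volume."""
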