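"""Geometric-error metrics, cross-method statistics and survival analysis.

The geometric error of a generated margin surface point is the exact
Euclidean distance from that point to the reference tumor voxel-center set,
minus the safe margin ``d_s``: negative errors are conservative (inside the
true offset surface), positive errors overshoot it.  Evaluation points are
the *outward boundary* voxels of a margin volume: voxels of the volume with
at least one 6-neighbour whose distance exceeds ``d_s`` while lying inside
bone (faces clipped by the bone surface are excluded -- there the volume is
bounded by anatomy, not by the margin).

Method comparison mirrors standard practice for paired accuracy studies:
Anderson-Darling normality per sample, one-sided Wilcoxon rank-sum
(normal approximation with continuity and tie correction), and the mean
difference with a pooled-variance Student t 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .errors import DomainError, EvaluationError
from .grid import MaskVolume, grid_to_points, require_same_grid
from .margin import DistanceMap

__all__ = [
    "ErrorReport",
    "ComparisonReport",
    "SurvivalCurve",
    "outward_boundary_points",
    "signed_errors",
    "error_summary",
    "compare_methods",
    "kaplan_meier",
]


@dataclass
class ErrorReport:
    """Per-point signed geometric errors (mm) and their summary statistics."""

    errors: np.ndarray
    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]
    max_abs: float

    def to_dict(self, method: str | None = None) -> dict:
        out = {
            "n_points": self.n,
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "ci95_mm": list(self.ci95),
            "max_abs_mm": self.max_abs,
        }
        if method is not None:
            out = {"method": method, **out}
        return out


@dataclass
class ComparisonReport:
    """Two-sample comparison of error distributions (a vs b, alternative a < b)."""

    ad_p_a: float
    ad_p_b: float
    ranksum_p: float
    mean_diff: float
    mean_diff_ci95: tuple[float, float]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "ad_p_a": self.ad_p_a,
            "ad_p_b": self.ad_p_b,
            "ranksum_p_one_sided": self.ranksum_p,
            "mean_diff_mm": self.mean_diff,
            "mean_diff_ci95_mm": list(self.mean_diff_ci95),
            "degenerate": self.degenerate,
        }


@dataclass
class SurvivalCurve:
    """Product-limit (Kaplan-Meier) survival estimate with Greenwood CI."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


_SHIFTS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
]


def _any_neighbor(mask: np.ndarray) -> np.ndarray:
    """True where at least one 6-neighbour of the voxel is true in ``mask``."""
    out = np.zeros_like(mask)
    for dx, dy, dz in _SHIFTS:
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, d in enumerate((dx, dy, dz)):
            if d == 1:
                src[ax] = slice(1, None)
                dst[ax] = slice(None, -1)
            elif d == -1:
                src[ax] = slice(None, -1)
                dst[ax] = slice(1, None)
        out[tuple(dst)] |= mask[tuple(src)]
    return out


def outward_boundary_points(
    margin_mask: MaskVolume,
    distance: DistanceMap,
    bone: MaskVolume,
    d_s: float,
) -> np.ndarray:
    """Centers of margin voxels facing the true outer margin boundary.

    A voxel qualifies when it is part of the margin volume (ring or coarse)
    and has a 6-neighbour with distance ``> d_s`` that lies inside bone.
    Voxels whose only outward neighbours are outside bone sit on a
    bone-clipped face and are excluded from the evaluation.
    """
    require_same_grid(margin_mask, bone, "margin and bone masks")
    if distance.grid.shape != margin_mask.shape:
        raise DomainError("distance map does not match the margin grid")
    beyond = (distance.values > d_s) & bone.occupancy
    sel = margin_mask.occupancy & _any_neighbor(beyond)
    if not sel.any():
        raise EvaluationError(
            "no outward boundary voxels: the margin volume is entirely clipped "
            "by the bone surface"
        )
    return grid_to_points(margin_mask.with_occupancy(sel))


def signed_errors(
    points: np.ndarray, tumor_ref: np.ndarray, d_s: float
) -> np.ndarray:
    """Exact nearest distance to the reference tumor point set, minus ``d_s``."""
    pts = np.asarray(points, dtype=float)
    ref = np.asarray(tumor_ref, dtype=float)
    if ref.size == 0 or pts.size == 0:
        raise EvaluationError("points and tumor reference must be non-empty")
    dist, _ = cKDTree(ref).query(pts)
    return dist - d_s


def error_summary(errors: np.ndarray) -> ErrorReport:
    """Mean, sample SD, normal-approximation 95% CI and max |error|."""
    e = np.asarray(errors, dtype=float).ravel()
    if e.size == 0:
        raise EvaluationError("cannot summarize an empty error sample")
    n = e.size
    mean = float(e.mean())
    sd = float(e.std(ddof=1)) if n > 1 else 0.0
    half = 1.96 * sd / np.sqrt(n)
    return ErrorReport(
        errors=e,
        n=n,
        mean=mean,
        sd=sd,
        ci95=(mean - half, mean + half),
        max_abs=float(np.abs(e).max()),
    )


def compare_methods(err_a: np.ndarray, err_b: np.ndarray) -> ComparisonReport:
    """Compare two error samples; the alternative hypothesis is ``a < b``.

    Returns Anderson-Darling normality p-values, the one-sided rank-sum p
    (normal approximation with continuity and tie correction), and
    ``mean(b) - mean(a)`` with a pooled-variance t 95% CI -- positive when
    method ``b`` has larger errors.
    """
    from statsmodels.stats.diagnostic import normal_ad

    a = np.asarray(err_a, dtype=float).ravel()
    b = np.asarray(err_b, dtype=float).ravel()
    if a.size < 3 or b.size < 3:
        raise DomainError("each sample needs at least 3 values")

    degenerate = np.ptp(np.concatenate([a, b])) == 0.0
    if degenerate:
        ranksum_p = 0.5  # all ties: no evidence either way
    else:
        ranksum_p = float(
            stats.mannwhitneyu(a, b, alternative="less", method="asymptotic").pvalue
        )

    def _ad_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0.0:
            return 0.0  # a constant sample is maximally non-normal
        return float(normal_ad(x)[1])

    n, m = a.size, b.size
    diff = float(b.mean() - a.mean())
    sp2 = ((n - 1) * a.var(ddof=1) + (m - 1) * b.var(ddof=1)) / (n + m - 2)
    se = float(np.sqrt(sp2 * (1.0 / n + 1.0 / m)))
    tcrit = float(stats.t.ppf(0.975, n + m - 2))
    return ComparisonReport(
        ad_p_a=_ad_p(a),
        ad_p_b=_ad_p(b),
        ranksum_p=ranksum_p,
        mean_diff=diff,
        mean_diff_ci95=(diff - tcrit * se, diff + tcrit * se),
        degenerate=bool(degenerate),
    )


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit survival estimate from right-censored follow-up data.

    ``times`` are months from surgery to death or last follow-up; ``events``
    flags deaths (censored otherwise).  Deaths are processed before
    censorings at tied times.  The 95% CI uses Greenwood's variance on the
    log(-log) scale.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events, dtype=bool).ravel()
    if t.size == 0 or t.size != e.size:
        raise DomainError("times and events must be non-empty and aligned")
    if np.any(t <= 0):
        raise DomainError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    return SurvivalCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
    )
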