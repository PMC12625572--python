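# Methods

## Problem and model

Given two co-registered binary masks on an axis-aligned anisotropic voxel
grid — bone `V_b` and tumor `V_t` — and a safe margin `d_s` (mm), the
package computes the set of bone voxels whose Euclidean distance to the
*refined* tumor (the tumor restricted to bone, `V_b ∧ V_t`) is at most
`d_s`.  Geometry is physical throughout: in-plane spacings `S_x, S_y` (mm),
per-slice z positions `P_z^k` (mm, possibly non-uniform), in-plane origin at
the center of the up-left voxel.  The voxel→point map is
`(i·S_x + P_x, j·S_y + P_y, P_z^k)` with 0-based indices.

Assumptions: identity direction cosines (axis-aligned grids only — NIfTI
inputs with rotated affines are rejected rather than silently resampled);
strictly increasing slice positions; masks co-registered on the identical
grid.

## Pipeline and numerical choices

**ROI.** The refined tumor's bounding box (over voxel centers, in mm) is
grown by `d_s + ξ` per face and converted to inclusive index ranges with
floor semantics on `(coord − origin)/spacing` (a fuzz of 1e-9 absorbs float
noise; boxes beyond the scan are clamped with a warning).  Default
`ξ = 2 mm`: it only needs to exceed the discretization slack between the
voxelized and continuous margin surface, which is below one voxel diagonal
(≲ 1.3 mm) at clinical spacings.

**Distance transform.** `scipy.ndimage.distance_transform_edt` with
per-axis sampling — an *exact* separable Euclidean transform, not a chamfer
approximation; the error bounds below rely on exactness and on the
1-Lipschitz property of the distance field.  The coarse path uses
`(S_x, S_y, D̄)` with `D̄ = (P_z^n − P_z^1)/(n−1)`; the fine path uses the
recomputed fine spacings.  All threshold comparisons are inclusive (`≤`).

**Resampling.** Replication factors are the smallest odd integers
`C = 2⌈(S/S_t + 1)/2⌉ − 1` with target `S_t = 0.10 mm` by default, so
`Ŝ_x = S_x/C_x ≤ S_t` and likewise in y; along z,
`Ŝ_z = (P_z^n − P_z^1)/(n·C_z − 1)`.  Replication is two-stage (in-plane,
then z) to bound peak memory, and purely block-structured — no smoothing,
mask fractions are exactly preserved.  In-plane, oddness makes the `C`
sub-centers straddle the parent center symmetrically
(`P̂_x = P_x + (−C_x/2 + 0.5)·Ŝ_x`).

**Fine slice positions.** A per-slab replication convention cannot
simultaneously keep the fine z grid uniform and preserve slice endpoints;
for stacks of more than two slices the literal per-pair interpolation rule
degenerates (replicas cluster in the first half of each slab).  This
package assigns the `k`-th fine slice the z of the fractional original
index `u = k·(n−1)/(n·C_z−1)`, interpolated piecewise-linearly through the
original slice table.  Consequences: both stack endpoints are preserved; a
two-slice stack reproduces the shared-endpoint interpolation exactly; a
uniform stack resamples to an *exactly uniform* stack with step `Ŝ_z`, so
the scalar-spacing distance transform is physically exact there — the
property the sub-voxel accuracy claim rests on; non-uniform stacks are
followed proportionally, and the residual mismatch between the scalar
metric and true z positions is bounded by the local deviation of the stack
from uniformity.  A fine z center can drift from its replication parent's z
by up to (but never beyond) one mean gap near the stack ends.

**Ring and fusion.** The dangerous ring keeps fine voxels with
`d_s − 2·max(Ŝ) ≤ D̂ ≤ d_s`, clipped to the fine bone mask (clipping happens
before point conversion, mirroring the coarse path).  The fused point set
is the union of coarse-volume and ring voxel centers; exact duplicates are
kept by default (`dedupe=True` removes them; they are harmless for Delaunay
reconstruction).  Surface reconstruction — boundary triangles of the
Delaunay tetrahedralization — is for export/visualization only; no metric
depends on it.

## Error evaluation

The reference surface is the exact Euclidean distance to the fine-grid
tumor voxel-center set — the same set the fine distance map measures —
computed independently through a KD-tree.  Evaluation points are *outward
boundary* voxels: members of the margin volume with a 6-neighbour whose
distance exceeds `d_s` while inside bone (bone-clipped faces are excluded:
there the volume is bounded by anatomy, not by the margin).  The signed
error is (nearest distance − `d_s`); negative = conservative.

For the fused method this construction guarantees errors in
`(−max(Ŝ), 0]`: ring membership gives `D̂ ≤ d_s`, and the outward neighbour
forces `D̂ > d_s − step` by the Lipschitz property.  At clinical spacings
`max(Ŝ) ≈ 0.087 mm`, hence mean |error| ≤ 0.09 mm and max |error| ≤
0.09 mm on any phantom.  The same argument bounds the coarse-only
comparator by `max(S_x, S_y, D̄)` (≈ 0.8 mm).  A surface-based evaluation
could in principle produce small positive means (e.g. at mesh vertices
between voxel centers); the voxel-center convention used here cannot, which
is documented rather than patched.

**Statistics.** `error_summary` reports mean, sample SD, the normal 95% CI
(`±1.96·SD/√n`; n is 10³–10⁵ boundary points, so the normal approximation
is ample) and max |error|.  `compare_methods` reports Anderson–Darling
normality p per sample (statsmodels), the one-sided Wilcoxon rank-sum p via
the normal approximation with continuity and tie correction (the MATLAB
`ranksum` convention; exact enumeration is unnecessary at n = 20), and the
mean difference with a pooled-variance Student-t 95% CI — the convention
that reproduces the bundled cohort's published summaries.  `kaplan_meier`
is the product-limit estimator (lifelines), deaths before censorings at
ties, Greenwood variance with the log(−log) CI transform; the CI transform
is a package choice since conventions differ.

## Synthetic phantoms

`make_sphere_phantom` digitizes a ball of radius `r` (tumor) centered in a
cuboid bone block on a grid with default spacings (0.75, 0.75, 0.80) mm —
typical clinical CT anisotropy.  Defaults: `r = 4 mm`, bone half-widths
16 mm, sized for `d_s = 10 mm` so the margin sphere (radius 14 mm) stays
2 mm clear of the bone faces and the fine ROI (~396×396×369 voxels) runs in
about half a minute and ~1.5 GB.  The construction requires
`min(half_widths) ≥ r + d_s + max(spacing)`.  `make_nonuniform_z_phantom`
adds seeded uniform jitter to interior slice positions (endpoints fixed, so
the mean gap and the resampling plan are unchanged).  An ellipsoid variant
exists for robustness tests; it has no closed-form surface distance and
carries no precision claims.

What the phantoms do *not* emulate: realistic bone texture or intensities,
cortical breakthrough, concave tumor shapes, segmentation noise, or
registration error.  Passing phantom tests therefore validates the
geometric machinery (resampling bookkeeping, exact distances, ring bounds)
— not robustness to imperfect clinical masks.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `d_s` | required (10/15/20 typical) | mm | safe margin; must exceed the ring band `2·max(Ŝ)` |
| `S_t` | 0.10 | mm | target fine spacing; accuracy ~`max(Ŝ)`, cost ~`(S/S_t)³` |
| `ξ` | 2.0 | mm | ROI slack beyond `d_s` |
| `dedupe` | off | — | drop duplicate fused points |
| jitter fraction | 0 | — | phantom slice-z non-uniformity, < 0.3 |

## Degenerate inputs and edge cases

Empty bone∩tumor intersection, empty foreground, single-slice stacks,
non-positive margins, margins not exceeding the ring band, label maps with
more than two values, and rotated NIfTI affines all raise typed errors.  A
margin volume entirely clipped by the bone surface has no outward boundary
and raises at evaluation rather than reporting errors against the wrong
surface.  ROI boxes beyond the scan are clamped (margin truncated by the
field of view — a real clinical situation), with a logged warning.

## Known limitations

- Intraosseous margins only; soft-tissue extension of the tumor is ignored
  by construction (refinement intersects with bone).
- Axis-aligned geometry; oblique acquisitions must be resampled upstream.
- The scalar-spacing fine metric is exact only for uniform stacks; strongly
  non-uniform stacks degrade gracefully (bounded by the local gap
  deviation) but are not exactly handled.
- The dilation baseline's structuring element (voxel ball of radius
  `round(d_s/S_x)`) is one concrete reading of voxel-unit dilation; it is
  meant to exhibit the anisotropy failure mode, not to be the best possible
  dilation.
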