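# safemargin

Fast and accurate **safe-margin volume generation** for computer-assisted
bone tumor resection planning.

In bone tumor surgery the surgeon must resect the tumor together with a
continuous layer of surrounding normal bone whose thickness is at least the
*safe margin* `d_s` (10/15/20 mm depending on tumor stage).  Planning cut
planes by eye cannot guarantee this in 3D.  This package computes, from two
co-registered binary masks — bone `V_b` and tumor `V_t` on an anisotropic
voxel grid — the **safe-margin volume**: the region consisting of the
(intraosseous) tumor plus all bone within `d_s` millimetres of it.  Cut
planes placed outside this volume are guaranteed to have adequate margins.

## Method

1. **Refinement** — only tumor inside bone can seed intraosseous margin
   growth: `V_t ← V_b ∧ V_t`.
2. **ROI crop** — all computation runs inside the tumor bounding box grown
   by `d_s + ξ` (ξ = 2 mm slack).
3. **Coarse volume** — the exact anisotropic Euclidean distance transform
   `D(i,j,k) = min_fg √(S_x²d_x² + S_y²d_y² + S_z²d_z²)` of the refined
   tumor on the original grid; thresholding `D ≤ d_s` and clipping to bone
   gives the coarse volume `V_d` (accuracy ~ the largest original spacing).
4. **Fine dangerous ring** — both ROIs are block-replicated by the smallest
   odd factors `C = 2⌈(S/S_t + 1)/2⌉ − 1` per axis so every spacing drops to
   `Ŝ ≤ S_t` (0.10 mm default); on that fine grid only the thin band
   `d_s − 2·max(Ŝ) ≤ D̂ ≤ d_s` (the *dangerous ring*) is kept, clipped to
   bone.
5. **Fusion** — the voxel centers of `V_d` and of the ring form the final
   point set `P̃_d`, optionally triangulated (Delaunay) for export.

Because the transform is exact and 1-Lipschitz, every outward-boundary point
of the ring lies within `max(Ŝ)` (≈ 0.087 mm at clinical spacings) of the
true `d_s`-offset surface — sub-voxel accuracy at a fraction of the cost of
processing the full fine grid.

The package also ships the two comparison methods (voxel-ball morphological
dilation; coarse-only distance transform), the predecessor brute-force
point-search method as an independent oracle, a deterministic sphere/
ellipsoid phantom generator with analytic ground truth, geometric-error
evaluation, and the accompanying statistics (Anderson–Darling, one-sided
Wilcoxon rank-sum, pooled-t effect sizes, Kaplan–Meier survival).

## Worked example

```python
import safemargin as sm

phantom = sm.make_sphere_phantom()   # r = 4 mm tumor in a bone block, 0.75/0.75/0.80 mm voxels
result = sm.generate_safe_margin_volume(phantom.bone, phantom.tumor, d_s=10.0, s_t=0.10)
print("replication factors:", result.params["replication_factors"])
print("fine spacings (mm): (%.4f, %.4f, %.4f)" % result.params["fine_spacings_mm"])
print("coarse voxels:", result.coarse_mask.n_true, " ring voxels:", result.ring_mask.n_true,
      " fused points:", len(result.fused_points))

boundary = sm.outward_boundary_points(result.ring_mask, result.fine_distance,
                                      result.fine_bone, 10.0)
errors = sm.signed_errors(boundary, sm.grid_to_points(result.fine_tumor), 10.0)
report = sm.error_summary(errors)
print("boundary points: %d  mean error: %.4f mm  95%% CI: (%.4f, %.4f)  max |error|: %.4f mm"
      % (report.n, report.mean, report.ci95[0], report.ci95[1], report.max_abs))
```

prints

```
replication factors: (9, 9, 9)
fine spacings (mm): (0.0833, 0.0833, 0.0870)
coarse voxels: 24779  ring voxels: 738122  fused points: 762901
boundary points: 302250  mean error: -0.0358 mm  95% CI: (-0.0359, -0.0357)  max |error|: 0.0866 mm
```

The 0.75/0.75/0.80 mm grid is replicated 9× per axis to reach the 0.10 mm
target.  The signed error of a boundary point is its exact distance to the
tumor point set minus `d_s`: all errors are negative (the generated surface
never overshoots the margin) and bounded by one fine spacing, so the mean
error is a few hundredths of a millimetre.

The same workflow is available from the shell:

```sh
safemargin phantom --out ph/
safemargin generate ph/bone.nrrd ph/tumor.nrrd --margin-mm 10 --out run/
safemargin evaluate ph/bone.nrrd ph/tumor.nrrd --margin-mm 10 --out report.json
safemargin km followup.csv --at 60
```

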