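import numpy as np
import pytest

import safemargin as sm


@pytest.fixture(scope="session")
def sphere_phantom():
    """Default clinical-scale sphere phantom (r=4 mm, 0.75/0.75/0.80 mm grid)."""
    return sm.make_sphere_phantom()


@pytest.fixture(scope="session")
def small_phantom():
    """Scaled-down phantom for fast end-to-end tests."""
    return sm.make_sphere_phantom(
        spacing=(0.5, 0.5, 0.6),
        bone_half_widths=(7.0, 7.0, 7.0),
        radius=2.0,
        d_s_max=4.0,
    )


@pytest.fixture(scope="session")
def small_run(small_phantom):
    """Full pipeline on the small phantom (d_s=4 mm, S_t=0.25 mm)."""
    return sm.generate_safe_margin_volume(
        small_phantom.bone, small_phantom.tumor, d_s=4.0, s_t=0.25, xi=1.0
    )


@pytest.fixture(scope="session")
def clinical_run(sphere_phantom):
    """Full pipeline at the study conditions: d_s=10 mm, S_t=0.10 mm, xi=2 mm.

    Shared by the precision checks so the ~0.5 GB fine grid is built once.
    """
    d_s = 10.0
    result = sm.generate_safe_margin_volume(
        sphere_phantom.bone, sphere_phantom.tumor, d_s=d_s, s_t=0.10, xi=2.0
    )
    boundary = sm.outward_boundary_points(
        result.ring_mask, result.fine_distance, result.fine_bone, d_s
    )
    errors = sm.signed_errors(
        boundary, sm.grid_to_points(result.fine_tumor), d_s
    )
    return {"phantom": sphere_phantom, "d_s": d_s, "result": result,
            "boundary": boundary, "errors": errors}


def random_mask_pair(rng, max_side=14, bone_fill=0.7, tumor_fill=0.15):
    """Random co-registered bone/tumor masks with anisotropic spacings."""
    shape = tuple(int(s) for s in rng.integers(4, max_side, 3))
    s_x, s_y = rng.uniform(0.4, 1.2, 2)
    d_z = rng.uniform(0.5, 1.5)
    z = np.arange(shape[2]) * d_z
    bone = sm.MaskVolume(rng.random(shape) < bone_fill, s_x, s_y, z)
    tumor = bone.with_occupancy(rng.random(shape) < tumor_fill)
    return bone, tumor
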