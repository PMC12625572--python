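"""Reading and writing mask volumes, point sets and meshes.

NRRD is the reference mask dialect (explicit per-axis spacings and origin);
NIfTI is accepted when its affine reduces to axis-aligned spacing + origin.
Non-uniform slice z positions are carried in a JSON sidecar
``{"slice_z": [...]}`` next to the image, since neither header can express
them.  Point sets are written as ASCII PLY and CSV in scanner/world
millimetres with no coordinate flips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import FormatError
from .grid import MaskVolume
from .margin import SafeMarginResult

__all__ = [
    "read_mask_volume",
    "write_mask_volume",
    "write_points_csv",
    "read_points_csv",
    "write_points_ply",
    "write_outputs",
]

_DIRECTION_TOL = 1e-6


def read_mask_volume(path, sidecar=None) -> MaskVolume:
    """Read a binary NRRD/NIfTI mask; geometry from the header.

    ``sidecar`` is an optional path to a JSON file with ``{"slice_z": [...]}``
    overriding the uniform z positions implied by the header.  A file with
    more than two distinct values is rejected (label maps are not masks);
    nonzero maps to true.
    """
    path = Path(path)
    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=_DIRECTION_TOL):
        raise FormatError(
            f"{path.name}: only axis-aligned (identity direction) grids are "
            "supported"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.unique(arr)
    if values.size > 2:
        raise FormatError(
            f"{path.name}: {values.size} distinct values; expected a binary mask"
        )
    occ = np.ascontiguousarray(arr.transpose(2, 1, 0) != 0)
    s_x, s_y, s_z = img.GetSpacing()
    if min(s_x, s_y, s_z) <= 0:
        raise FormatError(f"{path.name}: non-positive spacing in header")
    o_x, o_y, o_z = img.GetOrigin()
    if sidecar is not None:
        with open(sidecar) as fh:
            slice_z = np.asarray(json.load(fh)["slice_z"], dtype=float)
    else:
        slice_z = o_z + s_z * np.arange(occ.shape[2])
    return MaskVolume(occ, s_x, s_y, slice_z, o_x, o_y)


def write_mask_volume(mask: MaskVolume, path) -> list[Path]:
    """Write a mask as uint8 NRRD/NIfTI; returns the files written.

    Headers can only carry a scalar z spacing, so the mean gap is recorded
    there; when the slice table deviates from uniform by more than 1e-6 mm a
    ``<name>.slice_z.json`` sidecar with the exact positions is written too.
    """
    path = Path(path)
    arr = mask.occupancy.astype(np.uint8).transpose(2, 1, 0)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    z = mask.slice_z
    s_z = float(z[1] - z[0]) if z.size > 1 else 1.0
    img.SetSpacing((mask.spacing_x, mask.spacing_y, s_z))
    img.SetOrigin((mask.origin_x, mask.origin_y, float(z[0])))
    sitk.WriteImage(img, str(path), useCompression=True)
    written = [path]
    uniform = z.size < 2 or np.allclose(np.diff(z), s_z, atol=1e-6)
    if not uniform:
        sidecar = path.with_suffix(path.suffix + ".slice_z.json")
        sidecar.write_text(json.dumps({"slice_z": z.tolist()}))
        written.append(sidecar)
    return written


def write_points_csv(points: np.ndarray, path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(points, dtype=float), delimiter=",",
               header="x_mm,y_mm,z_mm", comments="", fmt="%.9f")
    return path


def read_points_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)


def write_points_ply(points: np.ndarray, path) -> Path:
    """ASCII PLY point cloud, float64 world millimetres."""
    import trimesh

    path = Path(path)
    cloud = trimesh.PointCloud(np.asarray(points, dtype=float))
    data = trimesh.exchange.ply.export_ply(cloud, encoding="ascii")
    path.write_bytes(data if isinstance(data, bytes) else data.encode())
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(result: SafeMarginResult, out_dir, mesh: bool = False) -> dict:
    """Persist a generation run: point set (PLY + CSV), masks, manifest.

    ``mesh=True`` additionally reconstructs and writes the Delaunay boundary
    surface as STL (export/visualization only).  Returns the manifest dict.
    """
    from . import __version__
    from .margin import reconstruct_surface

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    csv_path = write_points_csv(result.fused_points, out / "fused_points.csv")
    files["fused_points_csv"] = csv_path.name
    files["fused_points_ply"] = write_points_ply(
        result.fused_points, out / "fused_points.ply"
    ).name
    for written in write_mask_volume(result.coarse_mask, out / "coarse_mask.nrrd"):
        files.setdefault("coarse_mask", written.name)
    for written in write_mask_volume(result.ring_mask, out / "ring_mask.nrrd"):
        files.setdefault("ring_mask", written.name)
    if mesh:
        surface = reconstruct_surface(result.fused_points)
        surface.export(out / "fused_surface.stl")
        files["fused_surface_stl"] = "fused_surface.stl"

    manifest = {
        "version": __version__,
        "params": result.params,
        "n_fused_points": int(result.fused_points.shape[0]),
        "n_coarse_voxels": result.coarse_mask.n_true,
        "n_ring_voxels": result.ring_mask.n_true,
        "empty_ring": result.ring_mask.n_true == 0,
        "timings_s": result.timings,
        "files": files,
        "checksums": {"fused_points_csv": _sha256(csv_path)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
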