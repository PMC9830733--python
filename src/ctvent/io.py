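"""NIfTI reading/writing for grids, masks, and displacement fields.

Volumes are stored with a diagonal affine built from (spacing, origin) in
the package's (x, y, z) index convention; no rotation/shear is supported,
and a non-diagonal affine on load is rejected rather than silently
resampled.  NIfTI stores the affine in 32-bit floats, so spacing/origin
round-trip to ~1e-7 relative precision while voxel data round-trips
bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import DisplacementField, GridGeometry, ImageGrid, StructureMask

__all__ = [
    "write_volume",
    "read_volume",
    "read_mask",
    "write_mask",
    "write_displacement_field",
    "read_displacement_field",
]


def _affine(geometry: GridGeometry) -> np.ndarray:
    aff = np.diag(list(geometry.spacing) + [1.0])
    aff[:3, 3] = geometry.origin
    return aff


def _geometry_from(img: nib.Nifti1Image, shape) -> GridGeometry:
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off_diag, 0.0, atol=1e-5):
        raise ValueError("volume has a rotated/sheared affine; not supported")
    spacing = tuple(float(aff[i, i]) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise ValueError("volume has non-positive spacing on some axis")
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return GridGeometry(tuple(shape[:3]), spacing, origin)


def write_volume(volume: ImageGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64),
                          _affine(volume.geometry))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return ImageGrid(data, _geometry_from(img, data.shape))


def write_mask(mask: StructureMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.geometry))
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "") -> StructureMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(
            f"{path}: not a binary mask (values {uniq[:8]}); refusing to load "
            "as a structure"
        )
    label = label or Path(path).name.split(".")[0]
    return StructureMask(data.astype(bool), _geometry_from(img, data.shape), label)


def write_displacement_field(
    fld: DisplacementField, path: str | Path, split_components: bool = False
) -> None:
    """Store a displacement field as one 4-component volume (default) or as
    three scalar volumes with `_ux/_uy/_uz` suffixes."""
    if split_components:
        base = str(path)
        for suffix in (".nii.gz", ".nii"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        for c, name in enumerate(("ux", "uy", "uz")):
            img = nib.Nifti1Image(fld.u[..., c], _affine(fld.geometry))
            nib.save(img, f"{base}_{name}.nii.gz")
    else:
        img = nib.Nifti1Image(fld.u, _affine(fld.geometry))
        nib.save(img, str(path))


def read_displacement_field(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"{path}: expected a (nx, ny, nz, 3) displacement volume, got "
            f"shape {data.shape}"
        )
    return DisplacementField(data, _geometry_from(img, data.shape))


def check_common_grid(volumes: dict[str, ImageGrid | StructureMask]) -> GridGeometry:
    """Verify all named volumes share one grid; names the offender if not."""
    items = list(volumes.items())
    ref_name, ref = items[0]
    for name, vol in items[1:]:
        if not ref.geometry.close_to(vol.geometry):
            raise ValueError(
                f"volume '{name}' is not on the same grid as '{ref_name}'"
            )
    return ref.geometry
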