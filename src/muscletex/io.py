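"""NIfTI and CSV input/output.

Volumes are written with a diagonal affine carrying the voxel spacing, so a
round trip preserves both values and spacing.  Array axis order (x, y, z) is
stored as-is; no reorientation is performed.  Mask files carry the muscle
group and side in their filename (``<stem>_<ext|flex>_<left|right>_mask``),
which the loader parses back.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocess import PDFFVolume, ROIMask


def save_volume(vol: PDFFVolume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))
    return path


def load_volume(path: str | Path) -> PDFFVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PDFFVolume(np.clip(data, 0.0, 100.0), spacing)


def mask_filename(stem: str, muscle_group: str, side: str) -> str:
    return f"{stem}_{muscle_group.lower()}_{side}_mask.nii.gz"


def save_mask(mask: ROIMask, path: str | Path, spacing_mm=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), str(path))
    return path


def load_mask(path: str | Path) -> ROIMask:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    parts = name.split("_")
    # expected ..._<group>_<side>_mask
    group, side = "EXT", "left"
    if len(parts) >= 3 and parts[-1] == "mask":
        group = parts[-3].upper()
        side = parts[-2]
    return ROIMask(data, group, side)
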