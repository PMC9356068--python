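"""Volume I/O (NIfTI via nibabel, NRRD via SimpleITK) and manifest tables.

Files carry isotropic voxel spacing in their headers; arrays keep the
package's (slice, row, col) axis convention.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .phantom import BinaryMask, IntensityVolume


def write_volume(path, volume) -> None:
    """Write an IntensityVolume/BinaryMask to .nii/.nii.gz/.nrrd."""
    path = Path(path)
    arr = volume.values
    spacing = volume.spacing_mm
    data = arr.astype(np.uint8) if arr.dtype == bool else arr.astype(np.float32)
    if path.suffix == ".nrrd":
        img = sitk.GetImageFromArray(data)
        img.SetSpacing((spacing,) * 3)
        sitk.WriteImage(img, str(path))
    elif path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([spacing, spacing, spacing, 1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path, as_mask: bool = False):
    """Read a volume file back into the package's containers."""
    path = Path(path)
    if path.suffix == ".nrrd":
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)
        spacing = float(img.GetSpacing()[0])
    elif path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        spacing = float(abs(img.affine[0, 0]))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if as_mask:
        return BinaryMask(arr.astype(bool), spacing)
    return IntensityVolume(np.asarray(arr, dtype=float), spacing)


def write_manifest(path, rows: list[dict]) -> None:
    """Plain-text tab-separated sidecar manifest (id, side, seed, spec...)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
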