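"""NIfTI reading and writing.

Scalar volumes are stored as 3D NIfTI-1; displacement fields as 4D with
the vector component last, flagged as voxel-unit displacements in the
header description.  Data, dtype and affine survive a round trip.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

FIELD_DESCRIP = b"wavemorph displacement field, voxel units, vector-last"


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file; returns (data, affine).

    Displacement fields written by `write_nifti` come back as (3,H,W,D);
    scalar volumes as (H,W,D) in their stored dtype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types here
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 3:
        data = np.moveaxis(data, -1, 0)
    return data, img.affine


def write_nifti(array: np.ndarray, path, affine: np.ndarray | None = None):
    """Write a (H,W,D) volume or a (3,H,W,D) displacement field."""
    array = np.asarray(array)
    if affine is None:
        affine = np.eye(4)
    if array.ndim == 4 and array.shape[0] == 3:
        img = nib.Nifti1Image(np.moveaxis(array, 0, -1), affine)
        img.header["descrip"] = FIELD_DESCRIP
        img.header.set_intent("vector")
    elif array.ndim == 3:
        img = nib.Nifti1Image(array, affine)
    else:
        raise ValueError(f"expected (H,W,D) or (3,H,W,D), got {array.shape}")
    img.header.set_data_dtype(array.dtype)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
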