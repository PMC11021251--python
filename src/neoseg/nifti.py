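"""NIfTI-1 read/write for scalar and label volumes.

Geometry (affine, voxel spacing) is carried through unchanged; label
volumes are stored as unsigned integers.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .types import InvalidArgumentError, LabelVolume, Volume


def _spacing_from(img) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return tuple(float(v) for v in z)


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise InvalidArgumentError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    return Volume(data=data, spacing=_spacing_from(img), affine=np.asarray(img.affine))


def read_labels(path, table: dict[int, str] | None = None) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise InvalidArgumentError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    data = np.rint(data).astype(np.int32)
    return LabelVolume(
        data=data, spacing=_spacing_from(img), table=dict(table or {}),
        affine=np.asarray(img.affine),
    )


def write_volume(vol: Volume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def write_labels(labels: LabelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(labels.data, dtype=np.uint16), labels.affine)
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))
    return path


def write_mask(mask: np.ndarray, like: Volume | LabelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), like.affine)
    img.header.set_zooms(like.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0
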