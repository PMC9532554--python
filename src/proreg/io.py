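"""NIfTI readers/writers for volumes, label maps, and displacement fields.

Flows use a declared serialization dialect (no standard exists): a 4D
NIfTI whose 4th dimension has size 3, components being displacements
along the D, H, W array axes in voxel units; the header ``descrip``
field records the token ``proreg-flow:DHW-voxel``.  Any input affine is
accepted and carried through, but registration itself operates in voxel
space.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import Flow, LabelMap, Volume

__all__ = ["read_volume", "write_volume", "read_labels", "write_labels",
           "read_flow", "write_flow", "FLOW_DESCRIP"]

FLOW_DESCRIP = "proreg-flow:DHW-voxel"


class FormatError(ValueError):
    """Raised for unreadable or dimensionally wrong NIfTI inputs."""


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    try:
        return nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc


def read_volume(path) -> Volume:
    """Read a 3D scalar NIfTI volume (float data)."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D "
                          f"shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data, dtype=np.float32), spacing=spacing)


def write_volume(v: Volume, path) -> None:
    affine = np.diag([*v.spacing, 1.0])
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), str(path))


def read_labels(path) -> LabelMap:
    """Read an integer 3D NIfTI label map."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D label map, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(np.asarray(np.round(data), dtype=np.int32), spacing=spacing)


def write_labels(l: LabelMap, path) -> None:
    affine = np.diag([*l.spacing, 1.0])
    nib.save(nib.Nifti1Image(l.data.astype(np.int16), affine), str(path))


def read_flow(path) -> Flow:
    """Read a displacement field: 4D NIfTI with last dimension 3."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[3] != 3:
        raise FormatError(f"{path}: expected shape (D, H, W, 3), got {data.shape}")
    return Flow(np.moveaxis(np.asarray(data, dtype=np.float32), 3, 0))


def write_flow(u: Flow, path) -> None:
    data = np.moveaxis(u.data, 0, 3).astype(np.float32)
    img = nib.Nifti1Image(data, np.eye(4))
    img.header["descrip"] = FLOW_DESCRIP.encode()
    nib.save(img, str(path))
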