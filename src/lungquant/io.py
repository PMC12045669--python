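"""NIfTI volume I/O and JSON sidecars.

Volumes and label maps travel as ``.nii``/``.nii.gz``; spacing is taken
from the header zooms.  Orientation metadata in the affine is not
reinterpreted: files written by this package store the canonical
(right->left, ventral->dorsal, cranial->caudal) axis order, and readers of
external data may override the axis tuple explicitly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import CANONICAL_AXES, AcquisitionParams, RegionLabels, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "save_params",
    "load_params",
]


def read_volume(path, axes: tuple[str, str, str] = CANONICAL_AXES) -> Volume3D:
    """Load a 3D NIfTI volume.

    Spacing comes from the header zooms; ``axes`` declares the anatomical
    direction of each array axis (defaults to this package's canonical
    order, which is what :func:`write_volume` emits).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, file has {data.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) != 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or degenerate voxel spacing {zooms}")
    return Volume3D(data, tuple(float(z) for z in zooms), axes, allow_nan=bool(np.isnan(data).any()))


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI, preserving dtype and spacing."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed to write volume to {path}: {exc}") from exc


def read_labels(path, grid: Volume3D | None = None) -> RegionLabels:
    """Load an integer label map, optionally validating against a grid.

    With ``grid`` given, shape must match and spacing must agree within
    1e-3 mm, otherwise both geometries are reported.
    """
    vol = read_volume(path)
    if grid is not None and not vol.same_grid(grid):
        raise ValueError(
            f"label geometry {vol.shape} @ {vol.spacing} mm does not match "
            f"grid {grid.shape} @ {grid.spacing} mm"
        )
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise ValueError(f"{path}: label volume contains non-integer values")
        data = np.round(data).astype(np.int16)
    return RegionLabels(data)


def write_labels(labels: RegionLabels, spacing, path) -> None:
    vol = Volume3D(labels.labels.astype(np.int16), spacing)
    write_volume(vol, path)


def save_params(params: AcquisitionParams, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(params), indent=2) + "\n")


def load_params(path) -> AcquisitionParams:
    raw = json.loads(Path(path).read_text())
    raw["flip_angles_deg"] = tuple(raw["flip_angles_deg"])
    raw["voxel_mm"] = tuple(raw["voxel_mm"])
    return AcquisitionParams(**raw)
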