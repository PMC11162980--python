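"""Volume and atlas containers plus NIfTI I/O.

Volumes are plain 3D float arrays with isotropic (or per-axis) voxel sizes in
millimetres. An atlas is an integer parcellation on the same grid: label 0 is
background, labels 1..K are regions of interest (ROIs).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "AtlasLabels",
    "read_volume",
    "read_atlas",
    "write_volume",
    "write_atlas",
]


@dataclass
class VolumeGrid:
    """A 3D intensity volume with voxel spacing in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class AtlasLabels:
    """Integer ROI parcellation aligned with companion volumes.

    ``roi_names`` optionally maps label -> anatomical abbreviation; unnamed
    labels render as ``ROI_<label>``.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"atlas must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.round(arr)
            if not np.allclose(arr, rounded, atol=0):
                bad = arr[arr != rounded].flat[0]
                raise ValueError(f"atlas contains non-integer value {bad!r}")
            arr = rounded.astype(np.int32)
        self.labels = arr.astype(np.int32)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def roi_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def name_of(self, roi_id: int) -> str:
        return self.roi_names.get(int(roi_id), f"ROI_{int(roi_id)}")

    def mask(self, roi_id: int) -> np.ndarray:
        return self.labels == int(roi_id)

    def check_aligned(self, volume: VolumeGrid) -> None:
        if volume.shape != self.shape:
            raise ValueError(
                f"volume shape {volume.shape} does not match atlas shape {self.shape}"
            )


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def read_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(data, tuple(float(z) for z in zooms))


def read_atlas(path: str | Path) -> AtlasLabels:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return AtlasLabels(data, tuple(float(z) for z in zooms))


def write_volume(v: VolumeGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), _affine(v.voxel_size)), str(path))


def write_atlas(a: AtlasLabels, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(a.labels.astype(np.int32), _affine(a.voxel_size)), str(path))
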