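"""Core in-memory containers for 4D resting-state series, masks and motion traces.

All images in a cohort share one grid and one isotropic voxel size; the
affine is a plain scaling (no rotation), which is all the synthetic common
space needs.  NIfTI-1 is the on-disk format throughout, via nibabel.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TimeSeriesImage",
    "MotionTrace",
    "make_affine",
    "load_timeseries",
    "load_mask",
    "save_mask",
    "load_motion_trace",
]


def make_affine(voxel_size_mm: float) -> np.ndarray:
    """Scaling-only affine for an isotropic synthetic grid."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    return aff


@dataclasses.dataclass
class TimeSeriesImage:
    """A 4D voxel x time image with grid geometry and repetition time.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, n_volumes)
        BOLD-like signal, arbitrary units.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    tr_s : float
        Repetition time (sampling interval) in seconds.
    """

    data: np.ndarray
    voxel_size_mm: float
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("time series must have at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), make_affine(self.voxel_size_mm))
        img.header.set_zooms((self.voxel_size_mm,) * 3 + (self.tr_s,))
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclasses.dataclass
class MotionTrace:
    """Per-volume rigid-body realignment parameters.

    ``params`` has one row per volume and six columns: translations along
    x/y/z in mm, then rotations pitch/yaw/roll in radians.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be an (n_volumes, 6) array")
        if self.params.shape[0] < 1:
            raise ValueError("motion trace must cover at least one volume")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]

    def save(self, path: str | Path) -> None:
        # six-column whitespace-delimited text, realignment dialect
        np.savetxt(str(path), self.params, fmt="%.10f")


def load_timeseries(path: str | Path) -> TimeSeriesImage:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return TimeSeriesImage(data=data, voxel_size_mm=float(zooms[0]), tr_s=tr)


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5


def save_mask(mask: np.ndarray, voxel_size_mm: float, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), make_affine(voxel_size_mm)), str(path))


def load_motion_trace(path: str | Path) -> MotionTrace:
    arr = np.loadtxt(str(path))
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return MotionTrace(params=arr)
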