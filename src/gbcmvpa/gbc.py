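"""Voxel-wise global brain connectivity (degree-centrality) mapping.

For every gray-matter voxel, GBC sums (or counts) its suprathreshold
Pearson correlations with every other gray-matter voxel.  The default
"weighted-z" variant sums Fisher r-to-z transformed correlations over the
edges with r >= r_threshold (one-sided: negative correlations never
contribute); the "binary-count" variant counts those edges instead.  Maps
are then standardized across the mask (the zGBC scale) and Gaussian
smoothed within the mask.

The voxel x voxel correlation matrix is never materialized in full: voxels
are processed in blocks of rows, which gives results identical to the
naive double loop.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .images import TimeSeriesImage, make_affine

__all__ = ["GBCParams", "GBCMap", "compute_gbc_map", "standardize_map",
           "standardize_across_subjects", "smooth_map", "fwhm_to_sigma"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm * FWHM_TO_SIGMA


@dataclasses.dataclass
class GBCParams:
    r_threshold: float = 0.25
    variant: str = "weighted-z"  # or "binary-count"
    standardize: bool = True
    fwhm_mm: float = 6.0
    r_clamp: float = 1.0 - 1e-7
    block_size: int = 512

    def validate(self) -> None:
        if not (0.0 <= self.r_threshold < 1.0):
            raise ValueError("r_threshold must lie in [0, 1)")
        if self.variant not in ("weighted-z", "binary-count"):
            raise ValueError(f"unknown GBC variant {self.variant!r}")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        if not (0.0 < self.r_clamp < 1.0):
            raise ValueError("r_clamp must lie in (0, 1)")


@dataclasses.dataclass
class GBCMap:
    """Per-voxel connectivity degree over a gray-matter mask.

    ``values`` is ordered like ``np.argwhere(mask)`` (C order of voxel
    coordinates).
    """

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: float
    subject_id: str | None = None
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (int(self.mask.sum()),):
            raise ValueError("values must have one entry per mask voxel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GBC values must be finite")

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.mask.shape, fill, dtype=np.float64)
        vol[self.mask] = self.values
        return vol

    def save(self, path: str | Path, sidecar: bool = True) -> None:
        nib.save(nib.Nifti1Image(self.to_volume().astype(np.float32),
                                 make_affine(self.voxel_size_mm)), str(path))
        if sidecar:
            side = Path(str(path)).with_suffix("").with_suffix(".json")
            side.write_text(json.dumps(
                {"subject_id": self.subject_id, **self.provenance}, indent=2, sort_keys=True))


def compute_gbc_map(img: TimeSeriesImage, gm_mask: np.ndarray,
                    params: GBCParams | None = None) -> GBCMap:
    """Compute the (unstandardized, unsmoothed) GBC map of one subject.

    Zero-variance voxels receive GBC 0 (with a warning) and contribute no
    edges.  Self-connections are excluded.
    """
    params = params or GBCParams()
    params.validate()
    if gm_mask.shape != img.grid_shape:
        raise ValueError("mask geometry does not match the image")
    V = int(gm_mask.sum())
    if V < 2:
        raise ValueError("need at least 2 mask voxels")

    ts = img.data[gm_mask]  # (V, T)
    ts = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ts, axis=1)
    dead = norms == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance voxels set to GBC 0",
                      RuntimeWarning, stacklevel=2)
    Z = np.zeros_like(ts)
    Z[~dead] = ts[~dead] / norms[~dead, None]

    values = np.zeros(V)
    for start in range(0, V, params.block_size):
        stop = min(start + params.block_size, V)
        R = Z[start:stop] @ Z.T  # (block, V) correlations
        rows = np.arange(start, stop)
        R[rows - start, rows] = -np.inf  # exclude self
        above = R >= params.r_threshold
        if params.variant == "binary-count":
            values[start:stop] = above.sum(axis=1)
        else:
            Rc = np.clip(R, -params.r_clamp, params.r_clamp)
            values[start:stop] = np.where(above, np.arctanh(Rc), 0.0).sum(axis=1)
    values[dead] = 0.0
    return GBCMap(values=values, mask=gm_mask, voxel_size_mm=img.voxel_size_mm,
                  provenance={"r_threshold": params.r_threshold, "variant": params.variant})


def standardize_map(gmap: GBCMap) -> GBCMap:
    """Z-standardize across the mask: output mean 0, SD 1.

    Invariant under positive affine transforms of the input.  Raises on a
    constant map (zero SD).
    """
    if gmap.values.size < 2:
        raise ValueError("standardization needs at least 2 mask voxels")
    sd = gmap.values.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant map")
    vals = (gmap.values - gmap.values.mean()) / sd
    return dataclasses.replace(gmap, values=vals,
                               provenance={**gmap.provenance, "standardized": True})


def standardize_across_subjects(maps: list[GBCMap]) -> list[GBCMap]:
    """Alternative z-scaling: per voxel across subjects instead of per map
    across the mask.

    Preserves between-subject differences exactly (each voxel has mean 0,
    SD 1 over the cohort), at the price of maps no longer being
    standardized within subject.  Raises if any voxel is constant across
    subjects.
    """
    if len(maps) < 2:
        raise ValueError("across-subject standardization needs at least 2 maps")
    stack = np.vstack([m.values for m in maps])
    sd = stack.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("some voxels are constant across subjects")
    z = (stack - stack.mean(axis=0)) / sd
    return [dataclasses.replace(m, values=z[i],
                                provenance={**m.provenance, "standardized": "across-subjects"})
            for i, m in enumerate(maps)]


def smooth_map(gmap: GBCMap, fwhm_mm: float, voxel_size_mm: float | None = None) -> GBCMap:
    """Mask-restricted separable Gaussian smoothing.

    Uses sigma = fwhm / (2 sqrt(2 ln 2)) per axis, in voxel units.  The
    smoothed image is renormalized by the smoothed mask so values outside
    the mask never leak in and a constant map is returned unchanged.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return dataclasses.replace(gmap, values=gmap.values.copy())
    vs = voxel_size_mm if voxel_size_mm is not None else gmap.voxel_size_mm
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vs
    weight = gmap.mask.astype(np.float64)
    num = ndimage.gaussian_filter(gmap.to_volume(fill=0.0) * weight, sigma=sigma_vox)
    den = ndimage.gaussian_filter(weight, sigma=sigma_vox)
    vals = num[gmap.mask] / den[gmap.mask]
    return dataclasses.replace(gmap, values=vals,
                               provenance={**gmap.provenance, "fwhm_mm": fwhm_mm})
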