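"""In-scope preprocessing and head-motion quality control.

Covers the stages that operate on images already in a common space:
initial-volume discard, joint nuisance/trend regression, ideal band-pass
filtering, Power-convention framewise displacement (FD), and the
count-only scrubbing QC rules (no volumes are ever removed).

Filtering and regression are combined as a single orthogonal projection:
the ideal band-pass (an exact projection in the discrete Fourier basis) is
applied to both the data and the nuisance regressors, and the filtered data
are residualized on the filtered regressors.  The output is then band
limited, orthogonal to every nuisance regressor (raw or filtered), and the
whole operation is idempotent.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .images import MotionTrace, TimeSeriesImage

__all__ = [
    "PreprocParams",
    "QCParams",
    "QCReport",
    "discard_initial_volumes",
    "compute_fd_power",
    "evaluate_qc",
    "bandpass_projection",
    "clean_timeseries",
]


@dataclasses.dataclass
class PreprocParams:
    """Nuisance-regression and filtering parameters.

    Defaults follow the analysis pipeline this package implements: drop the
    first 10 volumes, first-order polynomial detrend, 0.01-0.08 Hz
    band-pass, and regression of the 6 motion parameters plus global, WM
    and CSF mean signals.
    """

    n_discard: int = 10
    detrend_order: int = 1
    band_hz: tuple[float, float] = (0.01, 0.08)
    regress_motion: bool = True
    regress_global: bool = True
    regress_wm: bool = True
    regress_csf: bool = True
    rotations_in_degrees: bool = False

    def validate(self, tr_s: float) -> None:
        low, high = self.band_hz
        nyquist = 0.5 / tr_s
        if not (0 <= low < high < nyquist):
            raise ValueError(f"band {self.band_hz} must satisfy 0 <= low < high < Nyquist ({nyquist:g} Hz)")
        if self.n_discard < 0 or self.detrend_order < 0:
            raise ValueError("n_discard and detrend_order must be non-negative")


@dataclasses.dataclass
class QCParams:
    fd_radius_mm: float = 50.0
    fd_flag_mm: float = 0.3
    mean_fd_max_mm: float = 0.3
    max_flag_fraction: float = 0.5


@dataclasses.dataclass
class QCReport:
    fd_mm: np.ndarray
    mean_fd_mm: float
    n_volumes: int
    flagged_count: int
    flagged_fraction: float
    max_flagged_volumes: float
    passed: bool

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fd_mm"] = [float(x) for x in self.fd_mm]
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def discard_initial_volumes(
    img: TimeSeriesImage, motion: MotionTrace | None, n_discard: int
) -> tuple[TimeSeriesImage, MotionTrace | None]:
    """Drop the first ``n_discard`` volumes from image and motion alike."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= img.n_volumes:
        raise ValueError(f"cannot discard {n_discard} of {img.n_volumes} volumes")
    if motion is not None and motion.n_volumes != img.n_volumes:
        raise ValueError("motion trace and image disagree on volume count")
    if n_discard == 0:
        return img, motion
    out_img = TimeSeriesImage(
        data=img.data[..., n_discard:], voxel_size_mm=img.voxel_size_mm, tr_s=img.tr_s
    )
    out_mot = None if motion is None else MotionTrace(params=motion.params[n_discard:])
    return out_img, out_mot


def compute_fd_power(motion: MotionTrace, radius_mm: float = 50.0,
                     rotations_in_degrees: bool = False) -> np.ndarray:
    """Power-convention framewise displacement.

    FD_t = sum |d translation| + radius * sum |d rotation|, with rotations
    converted to arc length on a sphere of ``radius_mm``; FD_1 = 0.
    Depends only on parameter differences, so it is invariant to constant
    offsets of the trace.
    """
    if radius_mm <= 0:
        raise ValueError("head radius must be positive")
    if motion.n_volumes < 2:
        raise ValueError("FD needs at least 2 volumes")
    rot = motion.rotations_rad
    if rotations_in_degrees:
        rot = np.deg2rad(rot)
    d_trans = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(rot, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + radius_mm * d_rot])
    return fd


def evaluate_qc(fd: np.ndarray, params: QCParams | None = None) -> QCReport:
    """Count-only scrubbing QC.

    A volume is flagged when FD > ``fd_flag_mm`` (strict).  The subject
    passes when mean FD < ``mean_fd_max_mm`` AND the flagged count <
    ``max_flag_fraction`` * n_volumes (both strict, e.g. 115 of 230).
    Volumes are never removed.
    """
    params = params or QCParams()
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("FD vector is empty")
    n = int(fd.size)
    flagged = int(np.sum(fd > params.fd_flag_mm))
    bound = params.max_flag_fraction * n
    mean_fd = float(fd.mean())
    return QCReport(
        fd_mm=fd,
        mean_fd_mm=mean_fd,
        n_volumes=n,
        flagged_count=flagged,
        flagged_fraction=flagged / n,
        max_flagged_volumes=bound,
        passed=(mean_fd < params.mean_fd_max_mm) and (flagged < bound),
    )


def bandpass_projection(x: np.ndarray, tr_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    """Ideal (rectangular) band-pass along the last axis.

    Keeps rFFT bins with low <= f <= high and zeroes the rest; an exact
    orthogonal projection, hence idempotent.
    """
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    coef = np.fft.rfft(x, axis=-1)
    coef[..., ~keep] = 0
    return np.fft.irfft(coef, n=n, axis=-1)


def _nuisance_matrix(img: TimeSeriesImage, motion: MotionTrace | None,
                     masks: dict[str, np.ndarray] | None, params: PreprocParams) -> np.ndarray:
    T = img.n_volumes
    cols = [np.ones(T)]
    t = np.linspace(-1.0, 1.0, T)
    for order in range(1, params.detrend_order + 1):
        cols.append(t ** order)
    if params.regress_motion and motion is not None:
        if motion.n_volumes != T:
            raise ValueError("motion regressors do not match the volume count")
        mot = motion.params.copy()
        if params.rotations_in_degrees:
            mot[:, 3:] = np.deg2rad(mot[:, 3:])
        cols.extend(mot.T)
    masks = masks or {}
    mean_specs = [("global", params.regress_global), ("wm", params.regress_wm),
                  ("csf", params.regress_csf)]
    for name, flag in mean_specs:
        if not flag:
            continue
        if name == "global":
            region = masks.get("global")
            if region is None:
                parts = [m for k, m in masks.items() if k in ("gm", "wm", "csf")]
                region = np.any(parts, axis=0) if parts else None
        else:
            region = masks.get(name)
        if region is not None and region.any():
            cols.append(img.data[region].mean(axis=0))
    return np.column_stack(cols)


def clean_timeseries(img: TimeSeriesImage, motion: MotionTrace | None = None,
                     masks: dict[str, np.ndarray] | None = None,
                     params: PreprocParams | None = None) -> TimeSeriesImage:
    """Joint nuisance regression + detrend + band-pass as one projection.

    The constant/polynomial trend, motion parameters and compartment mean
    signals form one regressor matrix; both data and regressors are ideal-
    band-pass filtered, then the filtered data are residualized on the
    filtered regressors by least squares (pseudoinverse when the matrix is
    rank deficient, with a warning).
    """
    params = params or PreprocParams()
    params.validate(img.tr_s)
    X = _nuisance_matrix(img, motion, masks, params)

    shape = img.data.shape
    Y = img.data.reshape(-1, shape[-1])
    Yf = bandpass_projection(Y, img.tr_s, params.band_hz)
    Xf = bandpass_projection(X.T, img.tr_s, params.band_hz).T

    # drop regressor columns annihilated by the filter (constant, trend)
    keep = np.linalg.norm(Xf, axis=0) > 1e-10 * max(1.0, np.linalg.norm(X))
    Xf = Xf[:, keep]
    if Xf.shape[1]:
        rank = np.linalg.matrix_rank(Xf)
        if rank < Xf.shape[1]:
            warnings.warn("nuisance regressor matrix is rank deficient; using pseudoinverse",
                          RuntimeWarning, stacklevel=2)
        beta, *_ = np.linalg.lstsq(Xf, Yf.T, rcond=None)
        Yf = Yf - (Xf @ beta).T
    return TimeSeriesImage(data=Yf.reshape(shape), voxel_size_mm=img.voxel_size_mm, tr_s=img.tr_s)
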