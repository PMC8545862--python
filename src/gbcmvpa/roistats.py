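"""ROI-level statistics: mean GBC extraction, (partial) Pearson correlation
with clinical scores under the pairwise Bonferroni rule, summary-statistic
one-way ANOVA, and the voxel-wise covariate-adjusted two-sample t-test.

The Bonferroni threshold implements the pairwise rule alpha / (n_rois *
(n_rois - 1) / 2) — 66 tests for 12 ROIs — as the default; a conventional
per-ROI alpha / n_rois option is provided (``bonferroni="per-roi"``).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .gbc import GBCMap

__all__ = [
    "CorrelationParams",
    "CorrelationResult",
    "roi_mean_values",
    "correlate",
    "anova_from_summary",
    "voxelwise_covariate_ttest",
]


@dataclasses.dataclass
class CorrelationParams:
    alpha: float = 0.05
    n_rois: int = 12
    bonferroni: str = "pairwise"  # "pairwise": alpha/(m(m-1)/2); "per-roi": alpha/m

    def corrected_threshold(self) -> float:
        if self.bonferroni == "pairwise":
            m = self.n_rois * (self.n_rois - 1) / 2.0
        elif self.bonferroni == "per-roi":
            m = float(self.n_rois)
        else:
            raise ValueError(f"unknown Bonferroni rule {self.bonferroni!r}")
        # with a single ROI there is nothing to correct for
        return self.alpha / m if m >= 1 else self.alpha


@dataclasses.dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    df: int
    corrected_threshold: float
    significant: bool
    partial: bool = False


def roi_mean_values(gbc_maps: list[GBCMap], cluster_voxels: np.ndarray) -> np.ndarray:
    """Per-subject arithmetic mean GBC over a cluster of voxels.

    ``cluster_voxels`` is an (n, 3) voxel index array; every voxel must lie
    inside each map's mask.
    """
    vox = np.atleast_2d(np.asarray(cluster_voxels, dtype=int))
    if vox.size == 0:
        raise ValueError("cluster is empty")
    out = np.empty(len(gbc_maps))
    for i, gmap in enumerate(gbc_maps):
        if not gmap.mask[tuple(vox.T)].all():
            raise ValueError("cluster extends outside the GBC mask")
        vol = gmap.to_volume()
        out[i] = vol[tuple(vox.T)].mean()
    return out


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


def correlate(x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None,
              params: CorrelationParams | None = None) -> CorrelationResult:
    """Pearson or partial Pearson correlation with a Bonferroni threshold.

    With covariates, both x and y are residualized on [1, covariates] and
    the residuals are correlated; the two-sided p uses df = n - 2 - k for k
    covariates.  An empty covariate set reduces exactly to plain Pearson.
    """
    params = params or CorrelationParams()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    k = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1] if C.size else 0
    n = len(x)
    if n < 3 + k:
        raise ValueError(f"need at least {3 + k} observations, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")

    if k:
        design = np.column_stack([np.ones(n), C])
        xr = _residualize(x, design)
        yr = _residualize(y, design)
        if xr.std() == 0 or yr.std() == 0:
            raise ValueError("covariates absorb all variance")
        r = float(np.corrcoef(xr, yr)[0, 1])
        df = n - 2 - k
        r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r_ * np.sqrt(df / (1 - r_ ** 2))
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        r, p = stats.pearsonr(x, y)
        r, p = float(r), float(p)
        df = n - 2

    thr = params.corrected_threshold()
    return CorrelationResult(r=r, p=p, n=n, df=df, corrected_threshold=thr,
                             significant=bool(p < thr), partial=k > 0)


def anova_from_summary(means, sds, ns) -> tuple[float, float]:
    """One-way ANOVA F and p from per-group means, SDs and sizes.

    Between-group SS from the group means about the grand mean; within-
    group SS = sum (n_g - 1) s_g^2; df = (k - 1, N - k).  Agrees exactly
    with a raw-data ANOVA when the summaries come from the same data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (len(means) == len(sds) == len(ns)) or len(means) < 2:
        raise ValueError("need matching summaries for at least 2 groups")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    k = len(means)
    N = ns.sum()
    grand = (ns * means).sum() / N
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds ** 2).sum()
    df1, df2 = k - 1, N - k
    if ss_within == 0:
        return (np.inf if ss_between > 0 else 0.0), (0.0 if ss_between > 0 else 1.0)
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p


def voxelwise_covariate_ttest(maps: np.ndarray, group: np.ndarray,
                              covariates: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Per-voxel group-effect t from the model value ~ group + covariates.

    ``maps`` is (n_subjects, n_voxels); ``group`` a binary indicator (the t
    is signed toward the group coded 1).  With no covariates this equals
    the classical pooled two-sample t.  Returns (t values, residual df).
    """
    Y = np.asarray(maps, dtype=float)
    g = np.asarray(group, dtype=float).ravel()
    n = Y.shape[0]
    if g.shape[0] != n:
        raise ValueError("group indicator must match the subject count")
    cols = [np.ones(n), g]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    df = n - rank
    if df < 1:
        raise ValueError("not enough subjects for the design")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)           # (p, V)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    return t, df
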