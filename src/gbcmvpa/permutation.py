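"""Permutation inference for classifier performance and discriminative maps.

One permutation scheme serves both questions: per repetition the subject
labels are shuffled uniformly at random (unrestricted), the full LOSOCV is
re-run with the permuted labels (the kernels do not depend on labels, so
per-fold centered kernels are computed once and reused), and both the
performance measures and the fold-averaged voxel weight map are recorded.

p-values follow the plain counting rule: p = #(null >= observed) / n_perm,
ties counting against the observed value; p = 0 is therefore reported as
"< 1/n_perm".  Voxel-wise weight tests are two-sided on |w|, with the sign
of the observed weight labelling each voxel positive- or negative-
discriminative.  Each weight map (observed and null alike) is normalized
to unit Euclidean norm before the voxel-wise comparison: a soft-margin fit
on shuffled labels is non-separable and accumulates far more dual mass
than the separable observed fit, so raw null weights are globally inflated
and the comparison must be of relative voxel contributions.  Under the
null the maps stay exchangeable, so the p-values remain calibrated.  Suprathreshold voxels are grouped into connected
components (26-neighbour by default), split by weight sign, and components
must exceed ``min_cluster_voxels`` (strict) to be kept.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .mvpa import (CVResult, FeatureMatrix, FoldModel, MetricsReport, ModelSpec,
                   _losocv_kernels, compute_metrics, losocv_with_labels)

__all__ = [
    "PermutationParams",
    "WeightMap",
    "Cluster",
    "ClusterSet",
    "PermutationResult",
    "empirical_p",
    "format_p",
    "permutation_test_performance",
    "compute_weight_map",
    "voxelwise_weight_significance",
    "permutation_analysis",
    "extract_clusters",
]


@dataclasses.dataclass
class PermutationParams:
    n_perm: int = 1000
    seed: int = 0
    voxel_p_threshold: float = 0.001
    min_cluster_voxels: int = 30
    connectivity: int = 26
    smoothed_estimator: bool = False  # (count+1)/(n_perm+1) instead of count/n_perm

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if not (0.0 < self.voxel_p_threshold < 1.0):
            raise ValueError("voxel_p_threshold must lie in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclasses.dataclass
class WeightMap:
    """Signed per-voxel classifier weights on a mask, optionally with
    permutation p-values."""

    weights: np.ndarray
    mask: np.ndarray
    p_values: np.ndarray | None = None
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (int(self.mask.sum()),):
            raise ValueError("weights must have one entry per mask voxel")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def weight_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.weights
        return vol

    def p_volume(self) -> np.ndarray:
        if self.p_values is None:
            raise ValueError("no p-values attached")
        vol = np.ones(self.mask.shape)
        vol[self.mask] = self.p_values
        return vol


@dataclasses.dataclass
class Cluster:
    voxels: np.ndarray  # (n, 3)
    size: int
    sign: str  # "positive" | "negative"
    peak_voxel: tuple[int, int, int]
    centroid_voxel: tuple[float, float, float]


@dataclasses.dataclass
class ClusterSet:
    clusters: list[Cluster]
    voxel_size_mm: float = 1.0

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters):
            rows.append({
                "cluster_id": i + 1, "size": c.size, "sign": c.sign,
                "peak_i": c.peak_voxel[0], "peak_j": c.peak_voxel[1], "peak_k": c.peak_voxel[2],
                "centroid_x_mm": c.centroid_voxel[0] * self.voxel_size_mm,
                "centroid_y_mm": c.centroid_voxel[1] * self.voxel_size_mm,
                "centroid_z_mm": c.centroid_voxel[2] * self.voxel_size_mm,
            })
        return pd.DataFrame(rows, columns=["cluster_id", "size", "sign", "peak_i", "peak_j",
                                           "peak_k", "centroid_x_mm", "centroid_y_mm",
                                           "centroid_z_mm"])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class PermutationResult:
    observed: MetricsReport
    null_metrics: dict[str, np.ndarray]
    p_values: dict[str, float]
    p_strings: dict[str, str]
    n_perm: int
    weight_map: WeightMap | None = None

    def save(self, path: str | Path) -> None:
        payload = {
            "n_perm": self.n_perm,
            "observed": self.observed.to_percent_dict(),
            "p_values": self.p_values,
            "p_strings": self.p_strings,
            "null_metrics": {k: [float(x) for x in v] for k, v in self.null_metrics.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def empirical_p(null: np.ndarray, observed: float, smoothed: bool = False) -> float:
    """p = #(null >= observed) / n_perm; ties count as extreme."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    count = int(np.sum(null >= observed))
    if smoothed:
        return (count + 1) / (null.size + 1)
    return count / null.size


def format_p(p: float, n_perm: int) -> str:
    return f"< {1.0 / n_perm:g}" if p == 0 else f"{p:g}"


def _fold_weights(fm: FoldModel, X: np.ndarray, center: bool) -> np.ndarray:
    """Primal weights of one fold from its dual coefficients:
    w = X_centered[train].T @ alpha (columns per class for OvR)."""
    Xt = X[fm.train_idx]
    if center:
        Xt = Xt - Xt.mean(axis=0)
    return Xt.T @ fm.alpha


def _average_weights(fms: list[FoldModel], X: np.ndarray, center: bool) -> np.ndarray:
    acc = None
    for fm in fms:
        w = _fold_weights(fm, X, center)
        acc = w if acc is None else acc + w
    return acc / len(fms)


def _unit_norm(w: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


_TRACKED = ("balanced_accuracy", "total_accuracy", "sensitivity", "specificity")


def _scalar_metrics(report: MetricsReport) -> dict[str, float]:
    out = {"balanced_accuracy": report.balanced_accuracy,
           "total_accuracy": report.total_accuracy}
    if len(report.classes) == 2:
        pos = str(report.classes[1])
        neg = str(report.classes[0])
        out["sensitivity"] = float(report.per_class.loc[pos, "sensitivity"])
        out["specificity"] = float(report.per_class.loc[pos, "specificity"])
    return out


def permutation_analysis(features: FeatureMatrix, model: ModelSpec,
                         params: PermutationParams,
                         compute_weights: bool = True) -> PermutationResult:
    """Run the observed LOSOCV and ``n_perm`` label-shuffled replicates.

    Returns performance p-values and (optionally) the fold-averaged weight
    map with two-sided voxel-wise permutation p-values, all from the same
    permutation stream.
    """
    params.validate()
    classes = features.classes()
    if compute_weights and len(classes) != 2:
        raise ValueError("weight maps are computed for binary contrasts")
    kernels = _losocv_kernels(features.X, model.center_features)
    n = features.n_subjects

    preds, scores, fms = losocv_with_labels(kernels, features.labels, model, classes,
                                            collect_models=compute_weights)
    observed = compute_metrics(CVResult(list(features.subject_ids), features.labels.copy(),
                                        preds, scores, classes))
    obs_scalars = _scalar_metrics(observed)
    w_obs = _average_weights(fms, features.X, model.center_features) if compute_weights else None

    rng = np.random.default_rng(params.seed)
    null_metrics: dict[str, list[float]] = {k: [] for k in obs_scalars}
    exceed = np.zeros_like(w_obs) if compute_weights else None
    for _ in range(params.n_perm):
        # one permutation applied across all folds of this repetition
        y_perm = features.labels[rng.permutation(n)]
        p_preds, p_scores, p_fms = losocv_with_labels(kernels, y_perm, model, classes,
                                                      collect_models=compute_weights)
        rep = compute_metrics(CVResult(list(features.subject_ids), y_perm, p_preds,
                                       p_scores, classes))
        for k, v in _scalar_metrics(rep).items():
            null_metrics[k].append(v)
        if compute_weights:
            w_perm = _average_weights(p_fms, features.X, model.center_features)
            exceed += np.abs(_unit_norm(w_perm)) >= np.abs(_unit_norm(w_obs))

    null_arrays = {k: np.asarray(v) for k, v in null_metrics.items()}
    p_values = {k: empirical_p(null_arrays[k], obs_scalars[k], params.smoothed_estimator)
                for k in obs_scalars}
    p_strings = {k: format_p(p, params.n_perm) for k, p in p_values.items()}

    wmap = None
    if compute_weights:
        if params.smoothed_estimator:
            p_vox = (exceed + 1) / (params.n_perm + 1)
        else:
            p_vox = exceed / params.n_perm
        # zero observed weight can only arise from a degenerate voxel; any
        # null |w| >= 0 ties it, so p = 1 there by the counting rule
        wmap = WeightMap(weights=w_obs, mask=np.ones(len(w_obs), dtype=bool),
                         p_values=p_vox,
                         provenance={"model": model.algorithm, "n_perm": params.n_perm,
                                     "folds_averaged": n})
    return PermutationResult(observed=observed, null_metrics=null_arrays,
                             p_values=p_values, p_strings=p_strings,
                             n_perm=params.n_perm, weight_map=wmap)


def permutation_test_performance(features: FeatureMatrix, model: ModelSpec,
                                 params: PermutationParams) -> PermutationResult:
    """Permutation significance of the LOSOCV performance measures."""
    return permutation_analysis(features, model, params, compute_weights=False)


def compute_weight_map(features: FeatureMatrix, model: ModelSpec,
                       mask: np.ndarray | None = None,
                       whole_sample_refit: bool = False) -> WeightMap:
    """Fold-averaged discriminative weight map (no p-values).

    With ``whole_sample_refit`` the model is instead fit once on all
    subjects and those primal weights are returned.
    """
    classes = features.classes()
    if len(classes) != 2:
        raise ValueError("weight maps are computed for binary contrasts")
    from .mvpa import _fit_fold  # local import to keep the public surface tidy

    if whole_sample_refit:
        all_idx = np.arange(features.n_subjects)
        K, _ = _build_full_kernel(features, model)
        fm = _fit_fold(model, K, features.labels, all_idx, classes)
        w = _fold_weights(fm, features.X, model.center_features)
    else:
        kernels = _losocv_kernels(features.X, model.center_features)
        _, _, fms = losocv_with_labels(kernels, features.labels, model, classes,
                                       collect_models=True)
        w = _average_weights(fms, features.X, model.center_features)
    m = mask if mask is not None else np.ones(len(w), dtype=bool)
    return WeightMap(weights=w, mask=m, provenance={"model": model.algorithm,
                                                    "whole_sample_refit": whole_sample_refit})


def _build_full_kernel(features: FeatureMatrix, model: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    from .mvpa import build_linear_kernel
    return build_linear_kernel(features.X, None, center=model.center_features)


def voxelwise_weight_significance(features: FeatureMatrix, model: ModelSpec,
                                  params: PermutationParams,
                                  mask: np.ndarray | None = None) -> WeightMap:
    """Weight map with two-sided (on |w|) voxel-wise permutation p-values."""
    res = permutation_analysis(features, model, params, compute_weights=True)
    wmap = res.weight_map
    if mask is not None:
        wmap = WeightMap(weights=wmap.weights, mask=mask, p_values=wmap.p_values,
                         provenance=wmap.provenance)
    return wmap


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def extract_clusters(p_map: WeightMap | np.ndarray, weight_map: WeightMap | np.ndarray = None,
                     params: PermutationParams | None = None,
                     voxel_size_mm: float = 1.0) -> ClusterSet:
    """Connected components of {v : p_v < threshold}, split by weight sign.

    Accepts either WeightMap objects (p and weights as 3D volumes derived
    from the mask) or plain 3D arrays.  Components with size <=
    ``min_cluster_voxels`` are discarded (strict '>' rule, e.g. 31 voxels
    survive a 30-voxel minimum but 30 do not).
    """
    params = params or PermutationParams()
    params.validate()
    if isinstance(p_map, WeightMap):
        p_vol = p_map.p_volume()
        w_vol = p_map.weight_volume() if weight_map is None else weight_map.weight_volume()
    else:
        p_vol = np.asarray(p_map, dtype=float)
        w_vol = np.asarray(weight_map, dtype=float)
    if p_vol.shape != w_vol.shape:
        raise ValueError("p map and weight map must share geometry")

    supra = p_vol < params.voxel_p_threshold
    structure = _connectivity_structure(params.connectivity)
    clusters: list[Cluster] = []
    for sign, sel in (("positive", w_vol > 0), ("negative", w_vol < 0)):
        labeled, n_comp = ndimage.label(supra & sel, structure=structure)
        for lab in range(1, n_comp + 1):
            vox = np.argwhere(labeled == lab)
            if len(vox) <= params.min_cluster_voxels:
                continue
            wvals = np.abs(w_vol[tuple(vox.T)])
            peak = tuple(int(x) for x in vox[int(np.argmax(wvals))])
            centroid = tuple(float(x) for x in vox.mean(axis=0))
            clusters.append(Cluster(voxels=vox, size=len(vox), sign=sign,
                                    peak_voxel=peak, centroid_voxel=centroid))
    clusters.sort(key=lambda c: -c.size)
    return ClusterSet(clusters=clusters, voxel_size_mm=voxel_size_mm)
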