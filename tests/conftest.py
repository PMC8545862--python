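"""Shared fixtures: small synthetic cohorts and feature sets.

Everything is generated programmatically with fixed seeds; session scope
keeps the more expensive cohorts to one generation per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from gbcmvpa.cohort import CohortConfig, EffectSpec, generate_cohort, generate_masks, pick_region
from gbcmvpa.mvpa import FeatureMatrix
from gbcmvpa.pipeline import Dataset, dataset_gbc_features


@pytest.fixture(scope="session")
def masks12():
    return generate_masks((12, 12, 12))


@pytest.fixture(scope="session")
def planted_binary_cohort(masks12):
    """2 x 20 subjects, one 40-voxel region with loading 1.0 vs 0.0."""
    gm, _, _ = masks12
    region = pick_region(gm, 40, seed=5)
    cfg = CohortConfig(
        group_sizes={"A": 20, "B": 20}, grid_shape=(12, 12, 12), n_volumes=240,
        effect_specs=[EffectSpec(region_voxels=region, loadings={"A": 1.0, "B": 0.0})],
        seed=42)
    return generate_cohort(cfg), region


@pytest.fixture(scope="session")
def planted_binary_features(planted_binary_cohort):
    cohort, region = planted_binary_cohort
    maps, reports, features = dataset_gbc_features(Dataset.from_cohort(cohort))
    return maps, reports, features, region


def gaussian_features(n_per_class: int, n_voxels: int, shift_cols=None, shift: float = 0.0,
                      n_classes: int = 2, seed: int = 0) -> FeatureMatrix:
    """Plain Gaussian feature matrices for classifier-level tests."""
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    X = rng.standard_normal((n, n_voxels))
    labels = np.repeat([f"g{i}" for i in range(n_classes)], n_per_class)
    if shift_cols is not None and shift:
        rows = np.where(labels == "g0")[0]
        X[np.ix_(rows, shift_cols)] += shift
    return FeatureMatrix(X=X, subject_ids=[f"s{i:03d}" for i in range(n)], labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
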