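"""Synthetic multi-group resting-state cohorts with planted connectivity effects.

The generator emulates the study design this package analyses: four
diagnostic groups (depressed essential tremor, non-depressed essential
tremor, primary depression, healthy controls) scanned for 240 volumes at
TR = 2 s, a shared gray-matter mask in a common space, subject head motion,
and clinical scores.  Group differences are planted as group-specific
loadings on band-limited latent signals shared by the voxels of designated
"circuit" regions: voxels sharing a latent with a larger loading become more
strongly intercorrelated, so their global brain connectivity rises.  For the
target group, the depression score is generated as a linear function of the
subject-level loading in a designated region, planting a connectivity-
severity correlation for the downstream ROI analysis.

No real data-generating model exists for the patient study being emulated;
every choice here is a documented stand-in (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .images import MotionTrace, TimeSeriesImage, save_mask

__all__ = [
    "CohortConfigError",
    "EffectSpec",
    "ClinicalModel",
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "generate_masks",
    "generate_motion_trace",
    "band_limited_signal",
    "pick_region",
    "generate_cohort",
    "write_cohort",
]

GROUPS = ("DET", "ET", "DP", "HC")

# Loose per-group clinical score distributions (mean, sd) emulating the
# study's demographic table; exact clinical realism is a non-goal.
_CLINICAL_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "DET": {"hdrs17": (18.98, 6.35), "hars14": (7.56, 3.47), "mmse": (26.00, 1.40),
            "age": (47.85, 15.66), "education_years": (14.73, 4.17)},
    "ET": {"hdrs17": (3.27, 1.60), "hars14": (3.73, 1.90), "mmse": (26.67, 1.71),
           "age": (46.16, 14.52), "education_years": (12.18, 3.95)},
    "DP": {"hdrs17": (25.31, 7.12), "hars14": (9.29, 4.93), "mmse": (25.67, 1.77),
           "age": (45.20, 13.25), "education_years": (11.95, 4.40)},
    "HC": {"hdrs17": (2.09, 1.19), "hars14": (2.02, 1.18), "mmse": (28.70, 1.35),
           "age": (46.60, 13.45), "education_years": (12.28, 3.49)},
}
_CLINICAL_DEFAULT = {"hdrs17": (5.0, 2.0), "hars14": (4.0, 2.0), "mmse": (27.0, 1.5),
                     "age": (50.0, 10.0), "education_years": (12.0, 3.0)}


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclasses.dataclass
class EffectSpec:
    """A planted regional connectivity effect.

    region_voxels : (n, 3) integer array of voxel indices (must lie in GM).
    loadings : group label -> weight on the region's shared latent signal.
    latent_band_hz : frequency band of the latent; kept inside the analysis
        band-pass (0.01-0.08 Hz) so planted structure survives filtering.
    loading_jitter : relative sd of per-subject loading variation, which
        gives the planted effect subject-level variance (and the clinical
        model something to correlate with).
    """

    region_voxels: np.ndarray
    loadings: dict[str, float]
    latent_band_hz: tuple[float, float] = (0.01, 0.08)
    loading_jitter: float = 0.15

    def __post_init__(self) -> None:
        self.region_voxels = np.atleast_2d(np.asarray(self.region_voxels, dtype=int))
        if self.region_voxels.shape[1] != 3:
            raise CohortConfigError("region_voxels must be an (n, 3) index array")


@dataclasses.dataclass
class ClinicalModel:
    """Linear link from planted subject loading to the depression score.

    For subjects of ``target_group``, hdrs17 = intercept + slope * loading_i
    + N(0, noise_sd), where loading_i is the subject's jittered loading in
    effect region ``target_effect`` (index into CohortConfig.effect_specs).
    """

    intercept: float = 11.0
    slope: float = 8.0
    noise_sd: float = 4.0
    target_group: str = "DET"
    target_effect: int = 0


@dataclasses.dataclass
class CohortConfig:
    group_sizes: dict[str, int]
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    n_volumes: int = 240
    tr_s: float = 2.0
    effect_specs: list[EffectSpec] = dataclasses.field(default_factory=list)
    global_loading: float = 0.3
    noise_sd: float = 1.0
    motion_level: float = 0.02
    clinical_model: ClinicalModel = dataclasses.field(default_factory=ClinicalModel)
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise CohortConfigError("group_sizes must not be empty")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise CohortConfigError(f"group {g!r} needs at least 2 subjects, got {n}")
        if len(self.grid_shape) != 3 or any(d < 4 for d in self.grid_shape):
            raise CohortConfigError("grid_shape must be 3 dimensions, each >= 4")
        if self.n_volumes <= 10:
            raise CohortConfigError("n_volumes must exceed 10")
        if self.noise_sd <= 0:
            raise CohortConfigError("noise_sd must be positive")
        if self.motion_level < 0:
            raise CohortConfigError("motion_level must be non-negative")
        if self.tr_s <= 0:
            raise CohortConfigError("tr_s must be positive")
        for spec in self.effect_specs:
            missing = [g for g in self.group_sizes if g not in spec.loadings]
            if missing:
                raise CohortConfigError(f"effect spec lacks loadings for groups {missing}")


@dataclasses.dataclass
class SubjectRecord:
    subject_id: str
    group: str
    hdrs17: float
    hars14: float
    mmse: float
    age: float
    education_years: float
    image_ref: str | None = None
    motion_ref: str | None = None


@dataclasses.dataclass
class Cohort:
    """An in-memory synthetic cohort: one shared mask set, one image and
    motion trace per subject, and the subjects table."""

    config: CohortConfig
    subjects: list[SubjectRecord]
    images: dict[str, TimeSeriesImage]
    motions: dict[str, MotionTrace]
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray

    def subjects_table(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(s) for s in self.subjects]
        return pd.DataFrame(rows)[
            ["subject_id", "group", "hdrs17", "hars14", "mmse", "age", "education_years"]
        ]

    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def generate_masks(grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concentric ellipsoidal gray-matter / white-matter / CSF compartments.

    The "brain" is an ellipsoid filling 90% of the grid half-extents;
    within it, the normalized radius partitions a WM core (r <= 0.35/0.9),
    a GM shell (the largest compartment) and an outer CSF rim.
    Returns three pairwise-disjoint boolean masks.
    """
    grid_shape = tuple(int(d) for d in grid_shape)
    if len(grid_shape) != 3 or any(d < 4 for d in grid_shape):
        raise CohortConfigError("grid too small: need 3 axes with >= 4 voxels each")
    center = [(d - 1) / 2.0 for d in grid_shape]
    half = [max((d - 1) / 2.0, 1e-9) for d in grid_shape]
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in grid_shape], indexing="ij")
    r = np.sqrt(
        ((ii - center[0]) / half[0]) ** 2
        + ((jj - center[1]) / half[1]) ** 2
        + ((kk - center[2]) / half[2]) ** 2
    )
    brain = r <= 0.9
    wm = r <= 0.35
    gm = (r > 0.35) & (r <= 0.75)
    csf = brain & (r > 0.75)
    if not (gm.any() and wm.any() and csf.any()):
        raise CohortConfigError("grid too small to host GM, WM and CSF compartments")
    return gm, wm, csf


def pick_region(gm_mask: np.ndarray, n_voxels: int, seed: int | np.random.Generator = 0,
                exclude: np.ndarray | None = None) -> np.ndarray:
    """Pick a compact ``n_voxels``-voxel region inside the GM mask.

    Grows the region as the ``n_voxels`` GM voxels nearest (Euclidean, in
    voxel units) to a randomly chosen GM seed voxel, excluding any voxels
    in ``exclude``.  Returns an (n, 3) index array.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.argwhere(gm_mask)
    if exclude is not None and len(exclude):
        excl = {tuple(v) for v in np.atleast_2d(exclude)}
        coords = np.array([c for c in coords if tuple(c) not in excl])
    if len(coords) < n_voxels:
        raise CohortConfigError(f"GM mask has only {len(coords)} available voxels, need {n_voxels}")
    seed_vox = coords[rng.integers(len(coords))]
    d = np.linalg.norm(coords - seed_vox, axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d))
    return coords[order[:n_voxels]]


def band_limited_signal(n: int, tr_s: float, band_hz: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance random signal with power only in ``band_hz``.

    Synthesized in the frequency domain: Gaussian complex coefficients on
    the rFFT bins whose frequency lies in [low, high], zero elsewhere.
    """
    low, high = band_hz
    freqs = np.fft.rfftfreq(n, d=tr_s)
    inband = (freqs >= low) & (freqs <= high)
    if not inband.any():
        raise CohortConfigError("latent band contains no resolvable frequency bins")
    coef = np.zeros(len(freqs), dtype=complex)
    k = int(inband.sum())
    coef[inband] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    sig = np.fft.irfft(coef, n=n)
    sd = sig.std()
    if sd == 0:  # pragma: no cover - cannot happen with nonzero coefficients
        raise CohortConfigError("degenerate latent signal")
    return sig / sd


def generate_motion_trace(n_volumes: int, level: float,
                          seed: int | np.random.Generator = 0) -> MotionTrace:
    """Smooth random-walk realignment parameters, zero at the first volume.

    ``level`` sets the sd (mm) of per-volume translation increments;
    rotation increments use level/50 rad so that, on a 50 mm head sphere,
    their arc-length contribution matches the translations.
    """
    if n_volumes < 2:
        raise CohortConfigError("motion trace needs at least 2 volumes")
    if level < 0:
        raise CohortConfigError("motion level must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes - 1, 6))
    if n_volumes > 6:
        # mild temporal smoothing of increments; rescale to keep unit sd
        kernel = np.ones(5) / 5.0
        steps = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), 0, steps)
        steps *= np.sqrt(5.0)
    steps[:, :3] *= level
    steps[:, 3:] *= level / 50.0
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return MotionTrace(params=params)


def _clinical_scores(group: str, rng: np.random.Generator) -> dict[str, float]:
    table = _CLINICAL_TABLE.get(group, _CLINICAL_DEFAULT)
    out = {}
    for name, (mu, sd) in table.items():
        out[name] = float(rng.normal(mu, sd))
    out["hdrs17"] = max(out["hdrs17"], 0.0)
    out["hars14"] = max(out["hars14"], 0.0)
    out["mmse"] = float(np.clip(out["mmse"], 0.0, 30.0))
    out["age"] = max(out["age"], 18.0)
    out["education_years"] = max(out["education_years"], 0.0)
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort (images, motion, subjects table).

    Deterministic given ``config.seed``: a master SeedSequence spawns one
    independent stream per subject, so subject data do not depend on the
    order or sizes of other groups beyond the subject's position.
    """
    config.validate()
    gm, wm, csf = generate_masks(config.grid_shape)
    gm_coords = np.argwhere(gm)
    gm_index = {tuple(c): i for i, c in enumerate(gm_coords)}
    for spec in config.effect_specs:
        for vox in spec.region_voxels:
            if tuple(vox) not in gm_index:
                raise CohortConfigError(f"effect region voxel {tuple(vox)} outside the GM mask")

    ss = np.random.SeedSequence(config.seed)
    groups_in_order = [(g, i) for g in config.group_sizes for i in range(config.group_sizes[g])]
    child_seeds = ss.spawn(len(groups_in_order))

    n_gm = len(gm_coords)
    subjects: list[SubjectRecord] = []
    images: dict[str, TimeSeriesImage] = {}
    motions: dict[str, MotionTrace] = {}

    for idx, ((group, _), child) in enumerate(zip(groups_in_order, child_seeds)):
        rng = np.random.default_rng(child)
        sid = f"sub-{idx + 1:03d}"
        T = config.n_volumes

        gm_ts = np.zeros((n_gm, T))
        # global latent shared by all GM voxels (weak widespread correlation)
        if config.global_loading != 0:
            gm_ts += config.global_loading * band_limited_signal(T, config.tr_s, (0.01, 0.08), rng)

        subj_loadings = []
        for spec in config.effect_specs:
            lam = float(spec.loadings[group])
            lam_i = lam * (1.0 + spec.loading_jitter * rng.standard_normal()) if lam != 0 else 0.0
            lam_i = max(lam_i, 0.0)
            subj_loadings.append(lam_i)
            latent = band_limited_signal(T, config.tr_s, spec.latent_band_hz, rng)
            rows = np.array([gm_index[tuple(v)] for v in spec.region_voxels])
            gm_ts[rows] += lam_i * latent

        gm_ts += config.noise_sd * rng.standard_normal((n_gm, T))

        data = np.zeros(config.grid_shape + (T,))
        data[tuple(gm_coords.T)] = gm_ts
        # WM / CSF compartments: own weak common latents plus noise, so the
        # nuisance mean regressors carry genuine structure
        for mask in (wm, csf):
            coords = np.argwhere(mask)
            ts = 0.5 * band_limited_signal(T, config.tr_s, (0.01, 0.08), rng)
            ts = ts[None, :] + config.noise_sd * rng.standard_normal((len(coords), T))
            data[tuple(coords.T)] = ts
        outside = ~(gm | wm | csf)
        data[outside] = 0.2 * config.noise_sd * rng.standard_normal((int(outside.sum()), T))

        # baseline + per-voxel slow drift, removed downstream by detrending
        drift_slope = rng.normal(0.0, 0.3, size=config.grid_shape)
        tt = np.linspace(-1.0, 1.0, T)
        data += 100.0 + drift_slope[..., None] * tt[None, None, None, :]

        scores = _clinical_scores(group, rng)
        cm = config.clinical_model
        if group == cm.target_group and config.effect_specs and cm.target_effect < len(config.effect_specs):
            scores["hdrs17"] = max(
                cm.intercept + cm.slope * subj_loadings[cm.target_effect] + rng.normal(0.0, cm.noise_sd),
                0.0,
            )

        subjects.append(SubjectRecord(subject_id=sid, group=group, **scores))
        images[sid] = TimeSeriesImage(data=data, voxel_size_mm=config.voxel_size_mm, tr_s=config.tr_s)
        motions[sid] = generate_motion_trace(T, config.motion_level, rng) if config.motion_level > 0 \
            else MotionTrace(params=np.zeros((T, 6)))

    return Cohort(config=config, subjects=subjects, images=images, motions=motions,
                  gm_mask=gm, wm_mask=wm, csf_mask=csf)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort to disk: per-subject 4D NIfTI + motion text files,
    3D mask NIfTIs, subjects TSV, and a JSON manifest tying them together.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = cohort.config.voxel_size_mm
    save_mask(cohort.gm_mask, vs, outdir / "mask_gm.nii")
    save_mask(cohort.wm_mask, vs, outdir / "mask_wm.nii")
    save_mask(cohort.csf_mask, vs, outdir / "mask_csf.nii")

    manifest: dict = {
        "voxel_size_mm": vs,
        "tr_s": cohort.config.tr_s,
        "grid_shape": list(cohort.config.grid_shape),
        "masks": {"gm": "mask_gm.nii", "wm": "mask_wm.nii", "csf": "mask_csf.nii"},
        "subjects_table": "participants.tsv",
        "subjects": [],
    }
    for sub in cohort.subjects:
        img_name = f"{sub.subject_id}_bold.nii"
        mot_name = f"{sub.subject_id}_motion.txt"
        cohort.images[sub.subject_id].save(outdir / img_name)
        cohort.motions[sub.subject_id].save(outdir / mot_name)
        sub.image_ref = img_name
        sub.motion_ref = mot_name
        manifest["subjects"].append(
            {"subject_id": sub.subject_id, "group": sub.group,
             "image": img_name, "motion": mot_name}
        )

    table = cohort.subjects_table()
    table.to_csv(outdir / "participants.tsv", sep="\t", index=False, float_format="%.6f")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
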