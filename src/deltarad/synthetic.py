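"""Synthetic longitudinal cohorts with the statistical structure the pipeline
assumes: per-patient feature trajectories that drift multiplicatively week by
week, with class-linked drift magnitude and day-to-day lognormal noise.

Two modes are offered.  Feature mode emits a fraction-level feature table
directly (fast; used for the statistical stages).  Image mode emits per-
fraction 3D volumes with an ellipsoidal ROI whose in-ROI intensity histogram
follows a programmable skew-normal shape schedule and whose volume follows a
programmable shrink schedule (used to exercise extraction end to end).

The generative model for feature mode is

    X[p, i, f] = b[p, i] * d[class(p), i] ** (week(f) - 1) * eps[p, i, f]

with lognormal ``eps`` of unit mean and coefficient of variation ``noise_cv``.
Because the downstream delta is a ratio to baseline, a multiplicative model
keeps the planted signal scale-free.  Features are generated independently of
one another; correlation structure between features is not emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ImageVolume, ParameterError, ROIMask, write_nifti, write_nifti_mask
from .registry import adjusted_registry

# Default planted drifts: the positive ("significant dysphagia") class drifts
# upward in first-order skewness and slightly downward in GLCM homogeneity;
# every other feature drifts identically in both classes.
DEFAULT_DRIFT_FEATURES: tuple[tuple[str, float, float], ...] = (
    ("Global Skewness", 1.00, 1.05),
    ("GLCM Homogeneity", 1.00, 0.98),
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters for a synthetic cohort.

    ``drift_features`` maps feature names to per-week multiplicative drifts
    ``(negative class, positive class)``; class-linked signal lives entirely in
    the drift rate so that baseline-anchored deltas carry it.
    """

    n_patients: int = 43
    n_fractions: int = 35
    fractions_per_week: int = 5
    prevalence: float = 15 / 43
    drift_features: tuple[tuple[str, float, float], ...] = DEFAULT_DRIFT_FEATURES
    noise_cv: float = 0.05
    baseline_sigma: float = 0.3
    feature_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(adjusted_registry().names))
    image_mode: bool = False
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_shape: tuple[float, float, float] = (14.0, 11.0, 8.0)  # semi-axes, voxels
    skew_shape_start: float = 0.0
    skew_shape_drift: tuple[float, float] = (0.0, 0.5)  # per-week shape increment
    roi_shrink_per_fraction: float = 0.005
    intensity_loc: float = 60.0
    intensity_scale: float = 10.0
    background_loc: float = 20.0
    background_scale: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ParameterError("n_patients: need at least 2")
        if self.n_fractions % self.fractions_per_week != 0:
            raise ParameterError("n_fractions: must be divisible by fractions_per_week")
        if not 0.0 < self.prevalence < 1.0:
            raise ParameterError("prevalence: must lie strictly in (0, 1)")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv: must be >= 0")
        known = set(self.feature_names)
        for name, dn, dp in self.drift_features:
            if name not in known:
                raise ParameterError(f"drift_features: unknown feature {name!r}")
            if dn <= 0 or dp <= 0:
                raise ParameterError("drift_features: drifts must be > 0")
        if self.image_mode:
            for semi, n in zip(self.roi_shape, self.grid_shape):
                if semi <= 0 or 2 * semi + 2 > n:
                    raise ParameterError("roi_shape: ellipsoid must fit inside the grid")

    @property
    def n_weeks(self) -> int:
        return self.n_fractions // self.fractions_per_week

    def week_of_fraction(self, fraction: int) -> int:
        return 1 + (fraction - 1) // self.fractions_per_week


@dataclass
class SyntheticCohort:
    outcomes: pd.Series                       # patient_id -> {0, 1}
    truth: SyntheticCohortSpec
    features: pd.DataFrame | None = None      # long: patient_id, fraction, week, feature_name, value
    volumes: dict | None = None               # (patient_id, fraction) -> (ImageVolume, ROIMask)


def _patient_ids(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


def _assign_labels(spec: SyntheticCohortSpec, rng: np.random.Generator) -> pd.Series:
    """Deterministic labels: the first ceil(n * prevalence) patients of a
    seeded shuffle are positive, making the prevalence exact up to rounding."""
    pids = _patient_ids(spec.n_patients)
    n_pos = math.ceil(spec.n_patients * spec.prevalence)
    perm = rng.permutation(spec.n_patients)
    labels = np.zeros(spec.n_patients, dtype=int)
    labels[perm[:n_pos]] = 1
    return pd.Series(labels, index=pd.Index(pids, name="patient_id"), name="label")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


def generate_feature_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate a fraction-level feature table cohort; bit-reproducible per seed."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_labels, rng_base, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))

    outcomes = _assign_labels(spec, rng_labels)
    pids = outcomes.index.to_numpy()
    names = list(spec.feature_names)
    n_pat, n_frac, n_feat = spec.n_patients, spec.n_fractions, len(names)

    fractions = np.arange(1, n_frac + 1)
    weeks = 1 + (fractions - 1) // spec.fractions_per_week

    drift = np.ones((2, n_feat))
    for name, d_neg, d_pos in spec.drift_features:
        j = names.index(name)
        drift[0, j] = d_neg
        drift[1, j] = d_pos
    # per class: (n_frac, n_feat) multiplicative drift factor
    drift_f = drift[:, None, :] ** (weeks - 1)[None, :, None]

    baselines = rng_base.lognormal(mean=0.0, sigma=spec.baseline_sigma,
                                   size=(n_pat, n_feat))
    noise = _lognormal_noise(rng_noise, spec.noise_cv, (n_pat, n_frac, n_feat))
    cls = outcomes.to_numpy()
    values = baselines[:, None, :] * drift_f[cls] * noise

    df = pd.DataFrame({
        "patient_id": np.repeat(pids, n_frac * n_feat),
        "fraction": np.tile(np.repeat(fractions, n_feat), n_pat),
        "week": np.tile(np.repeat(weeks, n_feat), n_pat),
        "feature_name": np.tile(names, n_pat * n_frac),
        "value": values.reshape(-1),
    })
    return SyntheticCohort(outcomes=outcomes, truth=spec, features=df)


# ---------------------------------------------------------------------------
# image mode

def _ellipsoid_mask(grid: tuple[int, int, int], semi_axes: tuple[float, float, float]
                    ) -> np.ndarray:
    idx = np.indices(grid, dtype=np.float64)
    center = [(n - 1) / 2.0 for n in grid]
    q = sum(((idx[k] - center[k]) / semi_axes[k]) ** 2 for k in range(3))
    return q <= 1.0


def iter_image_fractions(spec: SyntheticCohortSpec
                         ) -> Iterator[tuple[str, int, ImageVolume, ROIMask]]:
    """Yield (patient_id, fraction, image, mask) in a fixed deterministic order."""
    spec.validate()
    if not spec.image_mode:
        raise ParameterError("image_mode: must be set for image cohorts")
    ss = np.random.SeedSequence(spec.seed)
    label_child, image_child = ss.spawn(2)
    outcomes = _assign_labels(spec, np.random.default_rng(label_child))
    patient_seeds = image_child.spawn(spec.n_patients)

    for pid, pseed in zip(outcomes.index, patient_seeds):
        rng = np.random.default_rng(pseed)
        cls = int(outcomes[pid])
        incr = spec.skew_shape_drift[cls]
        for f in range(1, spec.n_fractions + 1):
            w = spec.week_of_fraction(f)
            scale_f = (1.0 - spec.roi_shrink_per_fraction) ** ((f - 1) / 3.0)
            axes = tuple(a * scale_f for a in spec.roi_shape)
            mask = _ellipsoid_mask(spec.grid_shape, axes)
            n_roi = int(mask.sum())
            vox = rng.normal(spec.background_loc, spec.background_scale,
                             size=spec.grid_shape)
            shape_a = spec.skew_shape_start + incr * (w - 1)
            vox[mask] = stats.skewnorm.rvs(shape_a, loc=spec.intensity_loc,
                                           scale=spec.intensity_scale,
                                           size=n_roi, random_state=rng)
            yield (pid, f, ImageVolume(vox, spec.spacing), ROIMask(mask))


def generate_image_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Materialize an image cohort in memory.

    Intended for small specs (tests, demos); for full-size cohorts stream
    :func:`iter_image_fractions` to disk instead.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    outcomes = _assign_labels(spec, np.random.default_rng(ss.spawn(2)[0]))
    volumes = {(pid, f): (img, msk) for pid, f, img, msk in iter_image_fractions(spec)}
    return SyntheticCohort(outcomes=outcomes, truth=spec, volumes=volumes)


# ---------------------------------------------------------------------------
# on-disk formats

def write_feature_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.features.to_csv(out / "features.csv", index=False)
    cohort.outcomes.to_csv(out / "outcomes.csv")


def write_image_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(spec.seed)
    outcomes = _assign_labels(spec, np.random.default_rng(ss.spawn(2)[0]))
    outcomes.to_csv(out / "outcomes.csv")
    for pid, f, img, msk in iter_image_fractions(spec):
        write_nifti(img, out / f"{pid}_f{f:02d}_img.nii.gz")
        write_nifti_mask(msk, img, out / f"{pid}_f{f:02d}_mask.nii.gz")


def read_feature_cohort(features_csv: str | Path, outcomes_csv: str | Path
                        ) -> tuple[pd.DataFrame, pd.Series]:
    feats = pd.read_csv(features_csv)
    outc = pd.read_csv(outcomes_csv).set_index("patient_id")["label"]
    return feats, outc


def skewnorm_sample_skewness(shape: float) -> float:
    """Closed-form population skewness of a skew-normal with the given shape.

    Used to document / test the mapping from the planted shape schedule to the
    skewness the extractor recovers.
    """
    delta = shape / math.sqrt(1.0 + shape ** 2)
    m = delta * math.sqrt(2.0 / math.pi)
    return (4.0 - math.pi) / 2.0 * m ** 3 / (1.0 - m ** 2) ** 1.5
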