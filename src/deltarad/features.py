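"""IBSI-style radiomic feature extraction on discretized 3D ROIs.

Texture statistics follow the 3D "merged" aggregation convention: pair / run
counts are accumulated over the 13 unique distance-1 direction offsets and
summed into a single matrix before normalization.  Zones (GLSZM) and
neighborhoods (NGTDM) use 26-connectivity.  All computations are vectorized;
independent brute-force enumeration oracles live in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import (DegenerateROIError, DiscretizedROI, ImageVolume,
                         ROIMask, discretize, resample_isotropic)
from .registry import FeatureRegistry, default_registry

# The 13 unique direction offsets at Chebyshev distance 1 in 3D (one per
# antipodal pair).
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
)

_COARSENESS_CAP = 1.0e6


@dataclass
class FeatureVector:
    """Ordered feature_name -> value map with acquisition context."""

    values: dict[str, float]
    patient_id: str | None = None
    fraction: int | None = None
    week: int | None = None
    n_voxels: int | None = None

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class ExtractionConfig:
    iso_mm: float = 1.0
    discretization: str = "fixed_bin_count"
    discretization_param: float = 32
    registry: FeatureRegistry = field(default_factory=default_registry)


# ---------------------------------------------------------------------------
# shifting helper

def _shifted(arr: np.ndarray, off: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[v] = arr[v - off], boundary filled with ``fill``."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, o in zip(arr.shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# first order

def first_order_features(d: DiscretizedROI, raw_intensities: np.ndarray) -> dict[str, float]:
    """First-order intensity statistics on the raw in-ROI values.

    Moments are population moments; skewness and (excess) kurtosis are defined
    as 0 for a constant ROI.  Entropy is Shannon entropy (log2) of the
    discretized gray-level histogram.
    """
    x = np.asarray(raw_intensities, dtype=np.float64)
    if x.size == 0:
        raise DegenerateROIError("first-order features need >= 1 ROI voxel")
    mu = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(((x - mu) ** 3).mean() / sd ** 3)
        kurt = float(((x - mu) ** 4).mean() / sd ** 4 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    lv = d.roi_levels()
    p = np.bincount(lv)[1:].astype(np.float64)
    p = p[p > 0] / lv.size
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "Global Mean": mu,
        "Global Variance": var,
        "Global Skewness": skew,
        "Global Kurtosis": kurt,
        "Global Median": float(np.median(x)),
        "Global Minimum": float(x.min()),
        "Global Maximum": float(x.max()),
        "Global Energy": float((x ** 2).sum()),
        "Global Entropy": entropy,
    }


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(d: DiscretizedROI, offsets=OFFSETS_13) -> np.ndarray:
    """Symmetric co-occurrence count matrix summed over the given offsets."""
    L = d.levels
    ng = d.Ng
    counts = np.zeros(ng * ng, dtype=np.int64)
    for off in offsets:
        b = _shifted(L, tuple(-o for o in off))  # neighbor at v + off
        valid = (L > 0) & (b > 0)
        if valid.any():
            idx = (L[valid] - 1) * ng + (b[valid] - 1)
            counts += np.bincount(idx, minlength=ng * ng)
    mat = counts.reshape(ng, ng)
    return mat + mat.T


def glcm_features(d: DiscretizedROI, offsets=OFFSETS_13) -> dict[str, float]:
    mat = glcm_matrix(d, offsets)
    total = mat.sum()
    if total == 0:
        raise DegenerateROIError("GLCM degenerate: no valid neighbor pairs")
    p = mat / total
    ng = d.Ng
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # marginal (equal on both axes by symmetry)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    if var > 0:
        corr = float((((ii - mu) * (jj - mu) * p).sum()) / var)
    else:
        corr = 1.0
    nz = p[p > 0]
    return {
        "GLCM Energy": float((p ** 2).sum()),
        "GLCM Contrast": float(((ii - jj) ** 2 * p).sum()),
        "GLCM Correlation": corr,
        "GLCM Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "GLCM Entropy": float(-(nz * np.log2(nz)).sum()),
        "GLCM Dissimilarity": float((np.abs(ii - jj) * p).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(d: DiscretizedROI, offsets=OFFSETS_13) -> np.ndarray:
    """Run-length count matrix (Ng x Rmax) summed over the given directions."""
    L = d.levels
    rmax = max(L.shape)
    mat = np.zeros((d.Ng, rmax), dtype=np.int64)
    for off in offsets:
        prev = _shifted(L, off)
        cont = (L > 0) & (L == prev)
        nxt = _shifted(L, tuple(-o for o in off))
        ends = (L > 0) & (L != nxt)
        # propagate run lengths along the direction until fixpoint
        length = np.ones(L.shape, dtype=np.int64)
        for _ in range(rmax):
            new = np.where(cont, _shifted(length, off) + 1, 1)
            if np.array_equal(new, length):
                break
            length = new
        g = L[ends] - 1
        r = length[ends] - 1
        np.add.at(mat, (g, r), 1)
    return mat


def _glrlm_stats(mat: np.ndarray, n_voxels: int, n_directions: int) -> dict[str, float]:
    ns = mat.sum()
    if ns == 0:
        raise DegenerateROIError("GLRLM degenerate: no runs")
    p = mat / ns
    ng, rmax = mat.shape
    g = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    r = np.arange(1, rmax + 1, dtype=np.float64)[None, :]
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    mu_g = float((g[:, 0] * pg).sum())
    mu_r = float((r[0, :] * pr).sum())
    return {
        "GLRLM SRE": float((p / r ** 2).sum()),
        "GLRLM LRE": float((p * r ** 2).sum()),
        "GLRLM GLN": float((mat.sum(axis=1).astype(np.float64) ** 2).sum() / ns),
        "GLRLM RLN": float((mat.sum(axis=0).astype(np.float64) ** 2).sum() / ns),
        "GLRLM RP": float(ns / (n_voxels * n_directions)),
        "GLRLM LGRE": float((p / g ** 2).sum()),
        "GLRLM HGRE": float((p * g ** 2).sum()),
        "GLRLM SRLGE": float((p / (g ** 2 * r ** 2)).sum()),
        "GLRLM SRHGE": float((p * g ** 2 / r ** 2).sum()),
        "GLRLM LRLGE": float((p * r ** 2 / g ** 2).sum()),
        "GLRLM LRHGE": float((p * g ** 2 * r ** 2).sum()),
        "GLRLM GLV": float((p * (g - mu_g) ** 2).sum()),
        "GLRLM RLV": float((p * (r - mu_r) ** 2).sum()),
    }


def glrlm_features(d: DiscretizedROI, offsets=OFFSETS_13) -> dict[str, float]:
    return _glrlm_stats(glrlm_matrix(d, offsets), d.n_voxels, len(offsets))


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_zones(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """26-connected equal-level zones as parallel arrays (level, size, count)."""
    L = d.levels
    levels, sizes, counts = [], [], []
    for g in range(1, d.Ng + 1):
        binary = L == g
        if not binary.any():
            continue
        lab, nl = ndimage.label(binary, structure=_STRUCT_26)
        zs = np.bincount(lab.ravel())[1:]
        sz, ct = np.unique(zs, return_counts=True)
        levels.extend([g] * len(sz))
        sizes.extend(sz.tolist())
        counts.extend(ct.tolist())
    return (np.asarray(levels, dtype=np.float64),
            np.asarray(sizes, dtype=np.float64),
            np.asarray(counts, dtype=np.float64))


def glszm_features(d: DiscretizedROI) -> dict[str, float]:
    g, s, n = glszm_zones(d)
    nz = n.sum()
    if nz == 0:
        raise DegenerateROIError("GLSZM degenerate: no zones")
    p = n / nz
    mu_g = float((p * g).sum())
    mu_s = float((p * s).sum())
    # marginal sums over distinct levels / sizes for the non-uniformity terms
    gl_marg = {}
    sz_marg = {}
    for gi, si, ni in zip(g, s, n):
        gl_marg[gi] = gl_marg.get(gi, 0.0) + ni
        sz_marg[si] = sz_marg.get(si, 0.0) + ni
    return {
        "GLSZM SAE": float((p / s ** 2).sum()),
        "GLSZM LAE": float((p * s ** 2).sum()),
        "GLSZM GLN": float(sum(v ** 2 for v in gl_marg.values()) / nz),
        "GLSZM ZSN": float(sum(v ** 2 for v in sz_marg.values()) / nz),
        "GLSZM ZP": float(nz / d.n_voxels),
        "GLSZM LGZE": float((p / g ** 2).sum()),
        "GLSZM HGZE": float((p * g ** 2).sum()),
        "GLSZM GLV": float((p * (g - mu_g) ** 2).sum()),
        "GLSZM ZSV": float((p * (s - mu_s) ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM

_KERNEL_26 = np.ones((3, 3, 3), dtype=np.float64)
_KERNEL_26[1, 1, 1] = 0.0


def ngtdm_table(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_g, s_g) over ROI voxels with >= 1 valid 26-neighbor."""
    L = d.levels
    roi = (L > 0).astype(np.float64)
    neigh_sum = ndimage.correlate(L.astype(np.float64) * roi, _KERNEL_26,
                                  mode="constant", cval=0.0)
    neigh_cnt = ndimage.correlate(roi, _KERNEL_26, mode="constant", cval=0.0)
    valid = (L > 0) & (neigh_cnt > 0.5)
    if not valid.any():
        raise DegenerateROIError("NGTDM degenerate: no voxel has a valid neighbor")
    diff = np.abs(L[valid] - neigh_sum[valid] / neigh_cnt[valid])
    idx = L[valid] - 1
    n_g = np.bincount(idx, minlength=d.Ng).astype(np.float64)
    s_g = np.bincount(idx, weights=diff, minlength=d.Ng)
    return n_g, s_g, int(valid.sum())


def ngtdm_features(d: DiscretizedROI) -> dict[str, float]:
    n_g, s_g, nvc = ngtdm_table(d)
    p = n_g / nvc
    present = p > 0
    gi = np.arange(1, d.Ng + 1, dtype=np.float64)
    ngp = int(present.sum())

    ps = float((p * s_g).sum())
    coarseness = _COARSENESS_CAP if ps == 0 else min(1.0 / ps, _COARSENESS_CAP)

    if ngp > 1:
        pi = p[present][:, None]
        pj = p[present][None, :]
        ii = gi[present][:, None]
        jj = gi[present][None, :]
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1))
        contrast *= float(s_g.sum()) / nvc
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        si = s_g[present][:, None]
        sj = s_g[present][None, :]
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()) / nvc
        s_sum = float(s_g.sum())
        strength = (float(((pi + pj) * (ii - jj) ** 2).sum()) / s_sum
                    if s_sum > 0 else 0.0)
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "NGTDM Coarseness": coarseness,
        "NGTDM Contrast": contrast,
        "NGTDM Busyness": busyness,
        "NGTDM Complexity": complexity,
        "NGTDM Strength": strength,
    }


# ---------------------------------------------------------------------------
# geometry + orchestration

def roi_volume(mask: ROIMask, spacing: tuple[float, float, float]) -> float:
    """ROI volume in mm^3: foreground voxel count times voxel volume."""
    if not mask.voxels.any():
        raise DegenerateROIError("empty mask has no volume")
    return float(mask.n_voxels * np.prod(spacing))


def extract_all(img: ImageVolume, mask: ROIMask,
                config: ExtractionConfig | None = None,
                patient_id: str | None = None, fraction: int | None = None,
                week: int | None = None) -> FeatureVector:
    """Resample, discretize and compute the full registry feature vector."""
    cfg = config or ExtractionConfig()
    try:
        rimg, rmask = resample_isotropic(img, mask, cfg.iso_mm)
        d = discretize(rimg, rmask, cfg.discretization, cfg.discretization_param)
        raw = rimg.voxels[rmask.voxels]
        computed: dict[str, float] = {}
        computed.update(first_order_features(d, raw))
        computed.update(glcm_features(d))
        computed.update(glrlm_features(d))
        computed.update(glszm_features(d))
        computed.update(ngtdm_features(d))
        computed["Geometry Volume"] = roi_volume(rmask, rimg.spacing)
    except DegenerateROIError as err:
        raise DegenerateROIError(
            f"patient={patient_id} fraction={fraction}: {err}") from err
    values = {name: computed[name] for name in cfg.registry.names}
    return FeatureVector(values=values, patient_id=patient_id,
                         fraction=fraction, week=week, n_voxels=d.n_voxels)
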