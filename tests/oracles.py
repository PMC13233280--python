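"""Independent brute-force oracles for texture features and ICC.

Everything here is written as explicit Python loops over voxels, pairs, runs,
zones and neighborhoods, deliberately sharing no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

NEIGHBORS_26 = [(dx, dy, dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= v[k] < shape[k] for k in range(3))


# ---------------------------------------------------------------------------
# GLCM

def glcm_oracle(levels: np.ndarray, ng: int, offsets=OFFSETS_13) -> np.ndarray:
    mat = np.zeros((ng, ng), dtype=float)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for off in offsets:
                    v = (x + off[0], y + off[1], z + off[2])
                    if _inside(shape, v) and levels[v] > 0:
                        b = levels[v]
                        mat[a - 1, b - 1] += 1
                        mat[b - 1, a - 1] += 1
    return mat


def glcm_features_oracle(levels: np.ndarray, ng: int, offsets=OFFSETS_13) -> dict:
    mat = glcm_oracle(levels, ng, offsets)
    p = mat / mat.sum()
    mu = sum((i + 1) * p[i, :].sum() for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i, :].sum() for i in range(ng))
    out = {"GLCM Energy": 0.0, "GLCM Contrast": 0.0, "GLCM Homogeneity": 0.0,
           "GLCM Entropy": 0.0, "GLCM Dissimilarity": 0.0}
    num = 0.0
    for i in range(ng):
        for j in range(ng):
            pij = p[i, j]
            out["GLCM Energy"] += pij ** 2
            out["GLCM Contrast"] += (i - j) ** 2 * pij
            out["GLCM Homogeneity"] += pij / (1 + abs(i - j))
            out["GLCM Dissimilarity"] += abs(i - j) * pij
            if pij > 0:
                out["GLCM Entropy"] -= pij * math.log2(pij)
            num += (i + 1 - mu) * (j + 1 - mu) * pij
    out["GLCM Correlation"] = num / var if var > 0 else 1.0
    return out


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_oracle(levels: np.ndarray, ng: int, offsets=OFFSETS_13) -> np.ndarray:
    shape = levels.shape
    rmax = max(shape)
    mat = np.zeros((ng, rmax), dtype=float)
    for off in offsets:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    g = levels[x, y, z]
                    if g == 0:
                        continue
                    prev = (x - off[0], y - off[1], z - off[2])
                    if _inside(shape, prev) and levels[prev] == g:
                        continue  # not a run start
                    length = 1
                    cur = (x + off[0], y + off[1], z + off[2])
                    while _inside(shape, cur) and levels[cur] == g:
                        length += 1
                        cur = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                    mat[g - 1, length - 1] += 1
    return mat


def glrlm_features_oracle(levels: np.ndarray, ng: int, n_voxels: int,
                          offsets=OFFSETS_13) -> dict:
    mat = glrlm_oracle(levels, ng, offsets)
    ns = mat.sum()
    rmax = mat.shape[1]
    keys = {k: 0.0 for k in ["SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE",
                             "LRLGE", "LRHGE", "GLV", "RLV"]}
    mu_g = sum((g + 1) * mat[g, r] / ns for g in range(ng) for r in range(rmax))
    mu_r = sum((r + 1) * mat[g, r] / ns for g in range(ng) for r in range(rmax))
    for g in range(ng):
        for r in range(rmax):
            pr = mat[g, r] / ns
            gg, rr = g + 1, r + 1
            keys["SRE"] += pr / rr ** 2
            keys["LRE"] += pr * rr ** 2
            keys["LGRE"] += pr / gg ** 2
            keys["HGRE"] += pr * gg ** 2
            keys["SRLGE"] += pr / (gg ** 2 * rr ** 2)
            keys["SRHGE"] += pr * gg ** 2 / rr ** 2
            keys["LRLGE"] += pr * rr ** 2 / gg ** 2
            keys["LRHGE"] += pr * gg ** 2 * rr ** 2
            keys["GLV"] += pr * (gg - mu_g) ** 2
            keys["RLV"] += pr * (rr - mu_r) ** 2
    keys["GLN"] = sum(mat[g, :].sum() ** 2 for g in range(ng)) / ns
    keys["RLN"] = sum(mat[:, r].sum() ** 2 for r in range(rmax)) / ns
    keys["RP"] = ns / (n_voxels * len(offsets))
    return {f"GLRLM {k}": v for k, v in keys.items()}


# ---------------------------------------------------------------------------
# GLSZM

def glszm_zone_list(levels: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) per 26-connected zone via explicit flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    v = stack.pop()
                    size += 1
                    for off in NEIGHBORS_26:
                        w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                        if _inside(shape, w) and not seen[w] and levels[w] == g:
                            seen[w] = True
                            stack.append(w)
                zones.append((int(g), size))
    return zones


def glszm_features_oracle(levels: np.ndarray, ng: int, n_voxels: int) -> dict:
    zones = glszm_zone_list(levels)
    nz = len(zones)
    mu_g = sum(g for g, _ in zones) / nz
    mu_s = sum(s for _, s in zones) / nz
    out = {
        "GLSZM SAE": sum(1 / s ** 2 for _, s in zones) / nz,
        "GLSZM LAE": sum(s ** 2 for _, s in zones) / nz,
        "GLSZM ZP": nz / n_voxels,
        "GLSZM LGZE": sum(1 / g ** 2 for g, _ in zones) / nz,
        "GLSZM HGZE": sum(g ** 2 for g, _ in zones) / nz,
        "GLSZM GLV": sum((g - mu_g) ** 2 for g, _ in zones) / nz,
        "GLSZM ZSV": sum((s - mu_s) ** 2 for _, s in zones) / nz,
    }
    gl = {}
    sz = {}
    for g, s in zones:
        gl[g] = gl.get(g, 0) + 1
        sz[s] = sz.get(s, 0) + 1
    out["GLSZM GLN"] = sum(v ** 2 for v in gl.values()) / nz
    out["GLSZM ZSN"] = sum(v ** 2 for v in sz.values()) / nz
    return out


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_features_oracle(levels: np.ndarray, ng: int) -> dict:
    shape = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                vals = []
                for off in NEIGHBORS_26:
                    v = (x + off[0], y + off[1], z + off[2])
                    if _inside(shape, v) and levels[v] > 0:
                        vals.append(levels[v])
                if vals:
                    n[g - 1] += 1
                    s[g - 1] += abs(g - sum(vals) / len(vals))
    nvc = n.sum()
    p = n / nvc
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    ps = sum(p[i] * s[i] for i in range(ng))
    coarseness = min(1 / ps, 1e6) if ps > 0 else 1e6
    contrast = busyness = complexity = strength = 0.0
    if ngp > 1:
        c = sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
        contrast = c / (ngp * (ngp - 1)) * (s.sum() / nvc)
        bd = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                 for i in present for j in present)
        busyness = ps / bd if bd > 0 else 0.0
        complexity = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                         for i in present for j in present) / nvc
        ssum = s.sum()
        strength = (sum((p[i] + p[j]) * (i - j) ** 2
                        for i in present for j in present) / ssum
                    if ssum > 0 else 0.0)
    return {"NGTDM Coarseness": coarseness, "NGTDM Contrast": contrast,
            "NGTDM Busyness": busyness, "NGTDM Complexity": complexity,
            "NGTDM Strength": strength}


# ---------------------------------------------------------------------------
# ICC via explicit ANOVA sums of squares

def icc_anova_oracle(matrix: np.ndarray) -> float:
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_total = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    row_means = [m[i, :].sum() / k for i in range(n)]
    ss_between = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_within = ss_total - ss_between
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 0.0
    return min(max((msb - msw) / denom, 0.0), 1.0)
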