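"""Gray-level texture matrices and their standard feature sets.

All functions take a 3D integer array ``levels`` where in-ROI voxels hold
discretized gray levels >= 1 and voxels outside the ROI are 0. Matrix
definitions and feature formulas follow the IBSI-aligned reference
radiomics feature set:

* GLCM  — symmetric co-occurrence at Chebyshev distance 1, all 13 unique
  3D directions, feature values averaged over directions (24 features);
* GLRLM — run-length matrices per direction, averaged (16 features);
* GLSZM — 26-connected equal-level zones, direction free (16 features);
* NGTDM — neighbourhood gray-tone difference over the 26-neighbourhood
  (5 features);
* GLDM  — gray-level dependence with Chebyshev distance 1 and level
  tolerance alpha; the dependence of a voxel is 1 (itself) plus the number
  of in-ROI neighbours whose level differs by at most alpha (14 features).

Gray levels entering the formulas are the actual level values, and Ng is
the number of distinct levels present in the ROI.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)

# 13 unique direction vectors covering the 26-neighbourhood up to sign
DIRECTIONS_13 = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
]

# all 26 neighbour offsets
OFFSETS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def _shift(arr: np.ndarray, d, fill=0) -> np.ndarray:
    """Shift so out[v] = arr[v + d], zero-filled at the borders."""
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, step in enumerate(d):
        n = arr.shape[ax]
        if abs(step) >= n:
            return out
        if step > 0:
            src[ax], dst[ax] = slice(step, n), slice(0, n - step)
        elif step < 0:
            src[ax], dst[ax] = slice(0, n + step), slice(-step, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------


def glcm_matrix(levels: np.ndarray, direction) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction.

    Returns an (Lmax, Lmax) count matrix indexed by level-1.
    """
    lv = np.asarray(levels, dtype=np.int64)
    lmax = int(lv.max())
    nb = _shift(lv, direction)
    ok = (lv > 0) & (nb > 0)
    a, b = lv[ok] - 1, nb[ok] - 1
    mat = np.zeros((lmax, lmax), dtype=np.float64)
    np.add.at(mat, (a, b), 1.0)
    return mat + mat.T  # symmetric: count each pair in both orders


def run_length_matrix(levels: np.ndarray, direction) -> np.ndarray:
    """Run-length counts for one direction: (Lmax, Rmax) indexed by
    (level-1, runlength-1)."""
    lv = np.asarray(levels, dtype=np.int64)
    lmax = int(lv.max())
    prev = _shift(lv, tuple(-s for s in direction))
    starts = np.argwhere((lv > 0) & (prev != lv))
    run_levels = lv[tuple(starts.T)]
    lengths = np.ones(len(starts), dtype=np.int64)
    pos = starts.astype(np.int64)
    active = np.arange(len(starts))
    d = np.asarray(direction, dtype=np.int64)
    while active.size:
        nxt = pos[active] + d
        inb = np.all((nxt >= 0) & (nxt < lv.shape), axis=1)
        cont = np.zeros(active.size, dtype=bool)
        if inb.any():
            vals = lv[tuple(nxt[inb].T)]
            cont[inb] = vals == run_levels[active[inb]]
        lengths[active[cont]] += 1
        pos[active[cont]] = nxt[cont]
        active = active[cont]
    rmax = int(lengths.max()) if len(lengths) else 1
    mat = np.zeros((lmax, rmax), dtype=np.float64)
    np.add.at(mat, (run_levels - 1, lengths - 1), 1.0)
    return mat


def size_zone_matrix(levels: np.ndarray) -> np.ndarray:
    """Zone-size counts: (Lmax, Smax) indexed by (level-1, size-1).
    Zones are 26-connected components of equal gray level."""
    lv = np.asarray(levels, dtype=np.int64)
    lmax = int(lv.max())
    struct = np.ones((3, 3, 3), dtype=int)
    rows, sizes_all = [], []
    for g in np.unique(lv[lv > 0]):
        lab, n = ndimage.label(lv == g, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        rows.extend([g - 1] * n)
        sizes_all.extend(sizes - 1)
    smax = int(max(sizes_all)) + 1 if sizes_all else 1
    mat = np.zeros((lmax, smax), dtype=np.float64)
    np.add.at(mat, (np.asarray(rows, dtype=int), np.asarray(sizes_all, dtype=int)), 1.0)
    return mat


def dependence_matrix(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Gray-level dependence counts: (Lmax, Dmax) indexed by
    (level-1, dependence-1); dependence includes the centre voxel."""
    lv = np.asarray(levels, dtype=np.int64)
    lmax = int(lv.max())
    inroi = lv > 0
    dep = np.ones(lv.shape, dtype=np.int64)
    for d in OFFSETS_26:
        nb = _shift(lv, d)
        dep += (np.abs(nb - lv) <= alpha) & (nb > 0) & inroi
    dmax = int(dep[inroi].max())
    mat = np.zeros((lmax, dmax), dtype=np.float64)
    np.add.at(mat, (lv[inroi] - 1, dep[inroi] - 1), 1.0)
    return mat


def ngtdm_table(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NGTDM components: (gray values i, counts n_i, sums s_i).

    s_i sums |i - A| over in-ROI voxels of level i, where A is the mean
    level of the voxel's in-ROI 26-neighbours; voxels without any in-ROI
    neighbour are excluded from both n_i and s_i.
    """
    lv = np.asarray(levels, dtype=np.float64)
    inroi = lv > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(lv * inroi, kernel, mode="constant")
    nb_cnt = ndimage.correlate(inroi.astype(np.float64), kernel, mode="constant")
    valid = inroi & (nb_cnt > 0)
    diffs = np.zeros_like(lv)
    diffs[valid] = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    gray = np.unique(lv[valid]).astype(np.int64)
    n_i = np.array([(lv[valid] == g).sum() for g in gray], dtype=np.float64)
    s_i = np.array([diffs[valid & (lv == g)].sum() for g in gray], dtype=np.float64)
    return gray, n_i, s_i


# ---------------------------------------------------------------------------
# feature calculators
# ---------------------------------------------------------------------------


def _glcm_features_single(mat: np.ndarray) -> dict[str, float]:
    keep = mat.sum(axis=1) > 0
    gray = (np.arange(mat.shape[0]) + 1)[keep].astype(np.float64)
    p = mat[np.ix_(keep, keep)]
    p = p / p.sum()
    ng = len(gray)
    i = gray[:, None]
    j = gray[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((px * gray).sum())
    uy = float((py * gray).sum())
    sx = float(np.sqrt((px * (gray - ux) ** 2).sum()))
    sy = float(np.sqrt((py * (gray - uy) ** 2).sum()))

    # p_{x+y} over k = 2..2*max, p_{x-y} over k = 0..max-1 (by value)
    ksum = (i + j).astype(np.int64)
    kdiff = np.abs(i - j).astype(np.int64)
    pxy_sum = np.zeros(int(ksum.max()) + 1)
    np.add.at(pxy_sum, ksum.ravel(), p.ravel())
    pxy_diff = np.zeros(int(kdiff.max()) + 1)
    np.add.at(pxy_diff, kdiff.ravel(), p.ravel())
    kv_sum = np.arange(len(pxy_sum), dtype=np.float64)
    kv_diff = np.arange(len(pxy_diff), dtype=np.float64)

    hxy = float(-(p * np.log2(p + _EPS)).sum())
    pxpy = px[:, None] * py[None, :]
    hxy1 = float(-(p * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())
    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())

    diff_avg = float((kv_diff * pxy_diff).sum())

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((p * i * j).sum())
    out["JointAverage"] = ux
    cdev = i + j - ux - uy
    out["ClusterProminence"] = float((p * cdev**4).sum())
    out["ClusterShade"] = float((p * cdev**3).sum())
    out["ClusterTendency"] = float((p * cdev**2).sum())
    out["Contrast"] = float((p * (i - j) ** 2).sum())
    if sx > 0 and sy > 0:
        out["Correlation"] = float(((p * i * j).sum() - ux * uy) / (sx * sy))
    else:
        out["Correlation"] = 1.0
    out["DifferenceAverage"] = diff_avg
    out["DifferenceEntropy"] = float(-(pxy_diff * np.log2(pxy_diff + _EPS)).sum())
    out["DifferenceVariance"] = float(((kv_diff - diff_avg) ** 2 * pxy_diff).sum())
    out["Id"] = float((p / (1.0 + kdiff)).sum())
    out["Idm"] = float((p / (1.0 + kdiff**2)).sum())
    out["Idmn"] = float((p / (1.0 + kdiff.astype(float) ** 2 / ng**2)).sum())
    out["Idn"] = float((p / (1.0 + kdiff.astype(float) / ng)).sum())
    out["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    offdiag = kdiff > 0
    out["InverseVariance"] = float((p[offdiag] / kdiff[offdiag] ** 2).sum())
    out["JointEnergy"] = float((p**2).sum())
    out["JointEntropy"] = hxy
    out["MCC"] = _glcm_mcc(p, px, py)
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float((kv_sum * pxy_sum).sum())
    out["SumEntropy"] = float(-(pxy_sum * np.log2(pxy_sum + _EPS)).sum())
    out["SumSquares"] = float((p * (i - ux) ** 2).sum())
    return out


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    ng = p.shape[0]
    if ng < 2:
        return 1.0
    # Q(i,j) = sum_k p(i,k) * p(j,k) / (px(i) * py(k))
    q = np.einsum("ik,jk->ij", p / px[:, None], p / py[None, :])
    eig = np.linalg.eigvals(q)
    eig = np.sort(np.real(eig))
    return float(np.sqrt(max(0.0, eig[-2]))) if len(eig) >= 2 else 1.0


def glcm_features(levels: np.ndarray) -> dict[str, float]:
    """GLCM features averaged over the 13 3D directions."""
    per_dir = []
    for d in DIRECTIONS_13:
        mat = glcm_matrix(levels, d)
        if mat.sum() > 0:
            per_dir.append(_glcm_features_single(mat))
    if not per_dir:
        raise ValueError("ROI too small for any co-occurrence pair")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _level_size_features(
    mat: np.ndarray, n_voxels: int, prefix_map: dict[str, str]
) -> dict[str, float]:
    """Shared GLRLM/GLSZM/GLDM feature formulas on a (level, size) matrix.

    ``prefix_map`` renames the generic feature keys to the family's
    conventional names (run/zone/dependence).
    """
    ns = mat.sum()
    p = mat / ns
    gray = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    size = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    pg = p.sum(axis=1)
    psz = p.sum(axis=0)
    mu_g = float((p * gray).sum())
    mu_s = float((p * size).sum())

    generic = {
        "SmallEmphasis": float((p / size**2).sum()),
        "LargeEmphasis": float((p * size**2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "SizeNonUniformity": float((mat.sum(axis=0) ** 2).sum() / ns),
        "SizeNonUniformityNormalized": float((psz**2).sum()),
        "Percentage": float(ns / n_voxels),
        "GrayLevelVariance": float((p * (gray - mu_g) ** 2).sum()),
        "SizeVariance": float((p * (size - mu_s) ** 2).sum()),
        "Entropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelEmphasis": float((p / gray**2).sum()),
        "HighGrayLevelEmphasis": float((p * gray**2).sum()),
        "SmallLowGrayLevelEmphasis": float((p / (gray**2 * size**2)).sum()),
        "SmallHighGrayLevelEmphasis": float((p * gray**2 / size**2).sum()),
        "LargeLowGrayLevelEmphasis": float((p * size**2 / gray**2).sum()),
        "LargeHighGrayLevelEmphasis": float((p * gray**2 * size**2).sum()),
    }
    return {new: generic[old] for new, old in prefix_map.items()}


_GLRLM_MAP = {
    "ShortRunEmphasis": "SmallEmphasis",
    "LongRunEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity": "SizeNonUniformity",
    "RunLengthNonUniformityNormalized": "SizeNonUniformityNormalized",
    "RunPercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "RunVariance": "SizeVariance",
    "RunEntropy": "Entropy",
    "LowGrayLevelRunEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelRunEmphasis": "HighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}

_GLSZM_MAP = {
    "SmallAreaEmphasis": "SmallEmphasis",
    "LargeAreaEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity": "SizeNonUniformity",
    "SizeZoneNonUniformityNormalized": "SizeNonUniformityNormalized",
    "ZonePercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "ZoneVariance": "SizeVariance",
    "ZoneEntropy": "Entropy",
    "LowGrayLevelZoneEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelZoneEmphasis": "HighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}

_GLDM_MAP = {
    "SmallDependenceEmphasis": "SmallEmphasis",
    "LargeDependenceEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "DependenceNonUniformity": "SizeNonUniformity",
    "DependenceNonUniformityNormalized": "SizeNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "DependenceVariance": "SizeVariance",
    "DependenceEntropy": "Entropy",
    "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}


def glrlm_features(levels: np.ndarray) -> dict[str, float]:
    """GLRLM features averaged over the 13 3D directions."""
    n_vox = int((np.asarray(levels) > 0).sum())
    per_dir = [
        _level_size_features(run_length_matrix(levels, d), n_vox, _GLRLM_MAP)
        for d in DIRECTIONS_13
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    n_vox = int((np.asarray(levels) > 0).sum())
    return _level_size_features(size_zone_matrix(levels), n_vox, _GLSZM_MAP)


def gldm_features(levels: np.ndarray, alpha: int = 0) -> dict[str, float]:
    n_vox = int((np.asarray(levels) > 0).sum())
    return _level_size_features(dependence_matrix(levels, alpha), n_vox, _GLDM_MAP)


def ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    gray, n_i, s_i = ngtdm_table(levels)
    nvp = n_i.sum()
    p_i = n_i / nvp
    g = gray.astype(np.float64)
    ngp = int((p_i > 0).sum())

    out: dict[str, float] = {}
    coarse_den = float((p_i * s_i).sum())
    out["Coarseness"] = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        ii = g[:, None]
        jj = g[None, :]
        pij = p_i[:, None] * p_i[None, :]
        out["Contrast"] = float(
            (pij * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nvp
        )
    else:
        out["Contrast"] = 0.0

    busy_den = float(np.abs(g[:, None] * p_i[:, None] - g[None, :] * p_i[None, :]).sum())
    out["Busyness"] = float((p_i * s_i).sum() / busy_den) if busy_den > 0 else 0.0

    if ngp > 1:
        pi_col = p_i[:, None]
        pj_row = p_i[None, :]
        si_col = s_i[:, None]
        sj_row = s_i[None, :]
        out["Complexity"] = float(
            (
                np.abs(g[:, None] - g[None, :])
                * (pi_col * si_col + pj_row * sj_row)
                / (pi_col + pj_row)
            ).sum()
            / nvp
        )
        s_sum = float(s_i.sum())
        out["Strength"] = (
            float(((pi_col + pj_row) * (g[:, None] - g[None, :]) ** 2).sum() / s_sum)
            if s_sum > 0
            else 0.0
        )
    else:
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
    return out
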