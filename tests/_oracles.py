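"""Independent brute-force oracles used by the test suite.

Everything here enumerates voxel pairs, runs, zones and neighbourhoods
directly with Python loops, or uses closed forms — deliberately naive and
structurally unrelated to the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

import numpy as np

NEIGHBOURS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def _inb(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


# ---------------------------------------------------------------------------
# matrix enumerations
# ---------------------------------------------------------------------------


def naive_glcm(levels, direction):
    """Symmetric co-occurrence counts as {(gi, gj): count}."""
    lv = np.asarray(levels)
    counts: dict = defaultdict(float)
    for p in np.ndindex(lv.shape):
        if lv[p] == 0:
            continue
        for d in (direction, tuple(-x for x in direction)):
            q = tuple(a + b for a, b in zip(p, d))
            if _inb(lv.shape, q) and lv[q] > 0:
                counts[(int(lv[p]), int(lv[q]))] += 1.0
    return dict(counts)


def naive_runs(levels, direction):
    """All (gray level, run length) runs along one direction."""
    lv = np.asarray(levels)
    runs = []
    for p in np.ndindex(lv.shape):
        if lv[p] == 0:
            continue
        prev = tuple(a - b for a, b in zip(p, direction))
        if _inb(lv.shape, prev) and lv[prev] == lv[p]:
            continue  # not a run start
        length = 1
        cur = p
        while True:
            nxt = tuple(a + b for a, b in zip(cur, direction))
            if _inb(lv.shape, nxt) and lv[nxt] == lv[cur]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(lv[p]), length))
    return runs


def naive_zones(levels):
    """All (gray level, zone size) 26-connected equal-level zones."""
    lv = np.asarray(levels)
    seen = np.zeros(lv.shape, dtype=bool)
    zones = []
    for p in np.ndindex(lv.shape):
        if lv[p] == 0 or seen[p]:
            continue
        g = lv[p]
        stack, size = [p], 0
        seen[p] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBOURS_26:
                q = tuple(a + b for a, b in zip(cur, d))
                if _inb(lv.shape, q) and not seen[q] and lv[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((int(g), size))
    return zones


def naive_dependencies(levels, alpha=0):
    """Per in-ROI voxel: (gray level, dependence) with the centre counted."""
    lv = np.asarray(levels)
    out = []
    for p in np.ndindex(lv.shape):
        if lv[p] == 0:
            continue
        dep = 1
        for d in NEIGHBOURS_26:
            q = tuple(a + b for a, b in zip(p, d))
            if _inb(lv.shape, q) and lv[q] > 0 and abs(int(lv[q]) - int(lv[p])) <= alpha:
                dep += 1
        out.append((int(lv[p]), dep))
    return out


def naive_ngtdm(levels):
    """{gray level: (count, sum |level - neighbour mean|)} over voxels with
    at least one in-ROI neighbour."""
    lv = np.asarray(levels)
    table: dict = defaultdict(lambda: [0, 0.0])
    for p in np.ndindex(lv.shape):
        if lv[p] == 0:
            continue
        nb = [
            int(lv[q])
            for d in NEIGHBOURS_26
            if _inb(lv.shape, q := tuple(a + b for a, b in zip(p, d))) and lv[q] > 0
        ]
        if not nb:
            continue
        g = int(lv[p])
        table[g][0] += 1
        table[g][1] += abs(g - sum(nb) / len(nb))
    return {g: (c, s) for g, (c, s) in table.items()}


# ---------------------------------------------------------------------------
# independent feature formulas over the enumerations
# ---------------------------------------------------------------------------


def glcm_sum_entropy(levels, directions):
    """Direction-averaged GLCM sum entropy from pair enumeration."""
    vals = []
    for d in directions:
        counts = naive_glcm(levels, d)
        total = sum(counts.values())
        if total == 0:
            continue
        psum: dict = defaultdict(float)
        for (gi, gj), c in counts.items():
            psum[gi + gj] += c / total
        vals.append(-sum(p * math.log2(p + np.spacing(1.0)) for p in psum.values()))
    return float(np.mean(vals))


def glcm_contrast(levels, directions):
    vals = []
    for d in directions:
        counts = naive_glcm(levels, d)
        total = sum(counts.values())
        if total == 0:
            continue  # directions with no pairs are excluded from the average
        vals.append(
            sum(c / total * (gi - gj) ** 2 for (gi, gj), c in counts.items())
        )
    return float(np.mean(vals))


def zones_features(levels):
    """A handful of GLSZM features straight from the zone list."""
    zones = naive_zones(levels)
    n = len(zones)
    glsizes: dict = defaultdict(int)
    for g, _ in zones:
        glsizes[g] += 1
    return {
        "GrayLevelNonUniformityNormalized": sum(v**2 for v in glsizes.values()) / n**2,
        "HighGrayLevelZoneEmphasis": sum(g**2 for g, _ in zones) / n,
        "LowGrayLevelZoneEmphasis": sum(1.0 / g**2 for g, _ in zones) / n,
        "SmallAreaEmphasis": sum(1.0 / s**2 for _, s in zones) / n,
        "LargeAreaEmphasis": sum(s**2 for _, s in zones) / n,
        "ZonePercentage": n / int((np.asarray(levels) > 0).sum()),
    }


def runs_features(levels, directions):
    """Direction-averaged GLRLM features from the run list."""
    per_dir = []
    n_vox = int((np.asarray(levels) > 0).sum())
    for d in directions:
        runs = naive_runs(levels, d)
        n = len(runs)
        per_dir.append(
            {
                "ShortRunEmphasis": sum(1.0 / r**2 for _, r in runs) / n,
                "LongRunEmphasis": sum(r**2 for _, r in runs) / n,
                "RunPercentage": n / n_vox,
                "HighGrayLevelRunEmphasis": sum(g**2 for g, _ in runs) / n,
            }
        )
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def dependence_features(levels, alpha=0):
    deps = naive_dependencies(levels, alpha)
    n = len(deps)
    mu_d = sum(d for _, d in deps) / n
    return {
        "LargeDependenceLowGrayLevelEmphasis": sum(d**2 / g**2 for g, d in deps) / n,
        "LowGrayLevelEmphasis": sum(1.0 / g**2 for g, d in deps) / n,
        "DependenceVariance": sum((d - mu_d) ** 2 for _, d in deps) / n,
        "SmallDependenceEmphasis": sum(1.0 / d**2 for _, d in deps) / n,
        "HighGrayLevelEmphasis": sum(g**2 for g, _ in deps) / n,
    }


def ngtdm_busyness(levels):
    table = naive_ngtdm(levels)
    nvp = sum(c for c, _ in table.values())
    num = sum(c / nvp * s for c, s in table.values())
    den = sum(
        abs(gi * ci / nvp - gj * cj / nvp)
        for gi, (ci, _) in table.items()
        for gj, (cj, _) in table.items()
    )
    return num / den if den > 0 else 0.0


def ngtdm_coarseness(levels):
    table = naive_ngtdm(levels)
    nvp = sum(c for c, _ in table.values())
    den = sum(c / nvp * s for c, s in table.values())
    return 1.0 / den if den > 0 else 1e6


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------


def pair_counting_auc(scores, labels):
    """AUC by direct enumeration of positive/negative pairs (ties = 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    wins = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
    )
    return wins / (len(pos) * len(neg))


def isotonic_minmax(y):
    """Exact monotone least-squares fit via the min-max closed form:
    fit[i] = max_{a<=i} min_{b>=i} mean(y[a..b])."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    csum = np.concatenate([[0.0], np.cumsum(y)])
    mean = lambda a, b: (csum[b + 1] - csum[a]) / (b + 1 - a)
    return np.array(
        [
            max(min(mean(a, b) for b in range(i, n)) for a in range(i + 1))
            for i in range(n)
        ]
    )


def paired_bootstrap_delong_p(scores_a, scores_b, labels, reps=20000, seed=0):
    """Two-sided p for the AUC difference from a paired bootstrap z-test."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    s_a, s_b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    y = np.asarray(labels).astype(int)
    n = len(y)
    diffs = []
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        if y[idx].min() == y[idx].max():
            continue
        diffs.append(
            pair_counting_auc_fast(s_a[idx], y[idx])
            - pair_counting_auc_fast(s_b[idx], y[idx])
        )
    observed = pair_counting_auc_fast(s_a, y) - pair_counting_auc_fast(s_b, y)
    sd = np.std(diffs, ddof=1)
    if sd == 0:
        return 1.0 if observed == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(observed) / sd))


def pair_counting_auc_fast(scores, labels):
    """Rank-based Mann-Whitney AUC (for the bootstrap loop only)."""
    from scipy import stats

    y = np.asarray(labels).astype(bool)
    r = stats.rankdata(scores)
    m = y.sum()
    return (r[y].sum() - m * (m + 1) / 2) / (m * (len(y) - m))
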