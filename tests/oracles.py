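"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in the most literal way possible — explicit
loops over voxel pairs, recursive flood fill, exhaustive scans — and never
calls the code under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

OFFSETS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def brute_glcm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """GLCM by explicit pair enumeration: symmetrize, normalize, average."""
    shape = levels.shape
    mats = []
    for off in OFFSETS_13:
        counts = np.zeros((n_levels, n_levels), dtype=float)
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    a = levels[x, y, z]
                    if a <= 0:
                        continue
                    xx, yy, zz = x + off[0], y + off[1], z + off[2]
                    if not (0 <= xx < shape[0] and 0 <= yy < shape[1]
                            and 0 <= zz < shape[2]):
                        continue
                    b = levels[xx, yy, zz]
                    if b <= 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1  # symmetrize
        total = counts.sum()
        if total > 0:
            mats.append(counts / total)
    assert mats, "no valid pairs in any direction"
    return sum(mats) / len(mats)


def brute_glszm(levels: np.ndarray, n_levels: int,
                connectivity: int = 26) -> dict[tuple[int, int], int]:
    """Zone counts {(level, size): count} by recursive flood fill."""
    if connectivity == 26:
        neigh = [d for d in itertools.product((-1, 0, 1), repeat=3)
                 if d != (0, 0, 0)]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                 (0, 0, 1), (0, 0, -1)]
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] <= 0 or seen[x, y, z]:
                    continue
                lv = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in neigh:
                        nx, ny, nz = cx + dx, cy + dy, cz + dz
                        if (0 <= nx < shape[0] and 0 <= ny < shape[1]
                                and 0 <= nz < shape[2] and not seen[nx, ny, nz]
                                and levels[nx, ny, nz] == lv):
                            seen[nx, ny, nz] = True
                            stack.append((nx, ny, nz))
                zones[(int(lv), size)] = zones.get((int(lv), size), 0) + 1
    return zones


def glcm_features_direct(p: np.ndarray) -> dict[str, float]:
    """Haralick features by direct double summation over all cells."""
    L = p.shape[0]
    energy = entropy = contrast = homogeneity = 0.0
    mu = 0.0
    for i in range(L):
        for j in range(L):
            mu += (i + 1) * p[i, j]
    s2 = 0.0
    for i in range(L):
        px_i = p[i, :].sum()
        s2 += (i + 1 - mu) ** 2 * px_i
    sij = 0.0
    variance = 0.0
    for i in range(L):
        for j in range(L):
            v = p[i, j]
            energy += v * v
            if v > 0:
                entropy -= v * math.log(v)
            contrast += (i - j) ** 2 * v
            homogeneity += v / (1 + abs(i - j))
            sij += (i + 1) * (j + 1) * v
            variance += (i + 1 - mu) ** 2 * v
    corr = math.nan if s2 == 0 else (sij - mu * mu) / s2
    return {
        "energy": energy,
        "entropy": entropy,
        "correlation": corr,
        "contrast": contrast,
        "homogeneity": homogeneity,
        "variance": variance,
        "max_probability": float(p.max()),
    }


def glszm_features_direct(zones: dict[tuple[int, int], int]) -> tuple[float, float]:
    """IV and SZV by direct summation over the zone dictionary."""
    nz = sum(zones.values())
    levels = {m for m, _ in zones}
    sizes = {n for _, n in zones}
    iv = sum(sum(c for (m, _), c in zones.items() if m == lvl) ** 2
             for lvl in levels) / nz
    szv = sum(sum(c for (_, n), c in zones.items() if n == sz) ** 2
              for sz in sizes) / nz
    return iv, szv


def grid_search_adc(signals, b_values, lo=0.0, hi=4.0e-3, tol=1e-9) -> float:
    """Log-domain least-squares ADC by golden-section-free bisected grid search.

    Minimizes sum over positive signals of (ln S - (c - b*D))^2 with c
    profiled out analytically for each candidate D.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    keep = s > 0
    s, b = s[keep], b[keep]
    logs = np.log(s)

    def sse(d):
        c = np.mean(logs + b * d)
        return float(np.sum((logs - (c - b * d)) ** 2))

    # iterative grid refinement down to tol resolution
    while hi - lo > tol:
        grid = np.linspace(lo, hi, 101)
        vals = [sse(d) for d in grid]
        k = int(np.argmin(vals))
        lo = grid[max(0, k - 1)]
        hi = grid[min(100, k + 1)]
    return (lo + hi) / 2


def pair_count_auc(pos, neg) -> float:
    """AUC by exhaustive enumeration of class pairs, ties worth 1/2."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def youden_scan(pos, neg):
    """Exhaustive Youden arg-max over all observed thresholds.

    Returns (J, sensitivity, specificity, threshold) with the positive
    call being score > threshold; ties broken toward higher specificity.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    best = None
    for t in np.unique(np.concatenate([pos, neg])):
        sens = float((pos > t).mean())
        spec = float((neg <= t).mean())
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (
                abs(j - best[0]) <= 1e-12 and spec > best[2]):
            best = (j, sens, spec, float(t))
    return best


def permutation_ttest_p(a, b, rng=None) -> float:
    """Exact two-sided permutation p for the difference in means (small n)."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)
    obs = abs(np.mean(a) - np.mean(b))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(np.mean(grp_a) - np.mean(grp_b)) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def bootstrap_auc_variance(scores, labels, n_boot=2000, seed=0) -> float:
    """Stratified-bootstrap variance of the Mann-Whitney AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        wins = (bp[:, None] > bn[None, :]).sum()
        ties = (bp[:, None] == bn[None, :]).sum()
        aucs[i] = (wins + 0.5 * ties) / (bp.size * bn.size)
    return float(np.var(aucs, ddof=1))
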