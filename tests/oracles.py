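"""Independent brute-force reference implementations for texture matrices.

Everything here is deliberately written as plain Python loops over voxels,
with no shared code with the package, so it can serve as an oracle for the
vectorized builders on tiny ROIs. Level 0 marks out-of-mask voxels.
"""

from itertools import product

import math

import numpy as np


def in_bounds(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def brute_glcm(levels, directions, displacement=1):
    """Symmetric co-occurrence probabilities by exhaustive pair enumeration."""
    levels = np.asarray(levels)
    G = int(levels.max())
    counts = np.zeros((G, G))
    for v in product(*[range(s) for s in levels.shape]):
        a = levels[v]
        if a == 0:
            continue
        for d in directions:
            w = tuple(v[i] + int(d[i]) * displacement for i in range(3))
            if not in_bounds(levels.shape, w):
                continue
            b = levels[w]
            if b == 0:
                continue
            counts[a - 1, b - 1] += 1
            counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_runs(levels, d):
    """All maximal same-level runs along direction d, as (level, length)."""
    levels = np.asarray(levels)
    d = tuple(int(c) for c in d)
    runs = []
    for v in product(*[range(s) for s in levels.shape]):
        a = levels[v]
        if a == 0:
            continue
        prev = tuple(v[i] - d[i] for i in range(3))
        if in_bounds(levels.shape, prev) and levels[prev] == a:
            continue  # not a run head
        length = 1
        w = tuple(v[i] + d[i] for i in range(3))
        while in_bounds(levels.shape, w) and levels[w] == a:
            length += 1
            w = tuple(w[i] + d[i] for i in range(3))
        runs.append((int(a), length))
    return runs


def brute_glrlm(levels, directions, shape_cap=None):
    """Run-length count matrix merged over directions."""
    levels = np.asarray(levels)
    G = int(levels.max())
    lmax = max(levels.shape)
    R = np.zeros((G, lmax))
    for d in directions:
        for g, ln in brute_runs(levels, d):
            R[g - 1, ln - 1] += 1
    return R


def brute_glszm(levels):
    """Size-zone counts via explicit 26-connected flood fill."""
    levels = np.asarray(levels)
    G = int(levels.max())
    seen = np.zeros(levels.shape, dtype=bool)
    neighbors = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    zones = []
    for v in product(*[range(s) for s in levels.shape]):
        if levels[v] == 0 or seen[v]:
            continue
        g = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for o in neighbors:
                w = tuple(u[i] + o[i] for i in range(3))
                if in_bounds(levels.shape, w) and not seen[w] and levels[w] == g:
                    seen[w] = True
                    stack.append(w)
        zones.append((int(g), size))
    smax = max(s for _, s in zones)
    Z = np.zeros((G, smax))
    for g, s in zones:
        Z[g - 1, s - 1] += 1
    return Z


def brute_ngtdm(levels):
    """(s, n) per gray level by explicit 26-neighborhood sweep."""
    levels = np.asarray(levels)
    G = int(levels.max())
    s = np.zeros(G)
    n = np.zeros(G)
    neighbors = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for v in product(*[range(si) for si in levels.shape]):
        a = levels[v]
        if a == 0:
            continue
        vals = []
        for o in neighbors:
            w = tuple(v[i] + o[i] for i in range(3))
            if in_bounds(levels.shape, w) and levels[w] != 0:
                vals.append(levels[w])
        if not vals:
            continue
        n[a - 1] += 1
        s[a - 1] += abs(a - sum(vals) / len(vals))
    return s, n


# ---------------------------------------------------------------------------
# direct formula evaluation of the non-modified features on oracle matrices


def formula_glcm(P):
    G = P.shape[0]
    mu = sum((i + 1) * P[i, j] for i in range(G) for j in range(G))
    var = sum((i + 1 - mu) ** 2 * P[i, j] for i in range(G) for j in range(G))
    out = {
        "glcm.contrast": sum(
            (i - j) ** 2 * P[i, j] for i in range(G) for j in range(G)
        ),
        "glcm.dissimilarity": sum(
            abs(i - j) * P[i, j] for i in range(G) for j in range(G)
        ),
        "glcm.homogeneity": sum(
            P[i, j] / (1 + abs(i - j)) for i in range(G) for j in range(G)
        ),
        "glcm.energy": sum(P[i, j] ** 2 for i in range(G) for j in range(G)),
        "glcm.variance": var,
        "glcm.entropy": -sum(
            P[i, j] * math.log2(P[i, j])
            for i in range(G)
            for j in range(G)
            if P[i, j] > 0
        ),
        "glcm.sum_average": sum(
            (i + j + 2) * P[i, j] for i in range(G) for j in range(G)
        ),
    }
    if var > 0:
        out["glcm.correlation"] = (
            sum((i + 1) * (j + 1) * P[i, j] for i in range(G) for j in range(G))
            - mu * mu
        ) / var
    return out


def formula_glrlm(R, n_voxels, n_directions):
    G, L = R.shape
    nr = R.sum()
    p = R / nr
    mu_g = sum((g + 1) * p[g, l] for g in range(G) for l in range(L))
    mu_l = sum((l + 1) * p[g, l] for g in range(G) for l in range(L))
    return {
        "glrlm.short_run_emphasis": sum(
            R[g, l] / (l + 1) ** 2 for g in range(G) for l in range(L)
        )
        / nr,
        "glrlm.long_run_emphasis": sum(
            R[g, l] * (l + 1) ** 2 for g in range(G) for l in range(L)
        )
        / nr,
        "glrlm.run_percentage": nr / (n_voxels * n_directions),
        "glrlm.low_gray_level_run_emphasis": sum(
            R[g, l] / (g + 1) ** 2 for g in range(G) for l in range(L)
        )
        / nr,
        "glrlm.high_gray_level_run_emphasis": sum(
            R[g, l] * (g + 1) ** 2 for g in range(G) for l in range(L)
        )
        / nr,
        "glrlm.short_run_low_gray_level_emphasis": sum(
            R[g, l] / ((g + 1) ** 2 * (l + 1) ** 2)
            for g in range(G)
            for l in range(L)
        )
        / nr,
        "glrlm.short_run_high_gray_level_emphasis": sum(
            R[g, l] * (g + 1) ** 2 / (l + 1) ** 2
            for g in range(G)
            for l in range(L)
        )
        / nr,
        "glrlm.long_run_low_gray_level_emphasis": sum(
            R[g, l] * (l + 1) ** 2 / (g + 1) ** 2
            for g in range(G)
            for l in range(L)
        )
        / nr,
        "glrlm.long_run_high_gray_level_emphasis": sum(
            R[g, l] * (g + 1) ** 2 * (l + 1) ** 2
            for g in range(G)
            for l in range(L)
        )
        / nr,
        "glrlm.gray_level_variance": sum(
            (g + 1 - mu_g) ** 2 * p[g, l] for g in range(G) for l in range(L)
        ),
        "glrlm.run_length_variance": sum(
            (l + 1 - mu_l) ** 2 * p[g, l] for g in range(G) for l in range(L)
        ),
    }


def formula_glszm(Z, n_voxels):
    G, S = Z.shape
    nz = Z.sum()
    p = Z / nz
    mu_g = sum((g + 1) * p[g, s] for g in range(G) for s in range(S))
    mu_s = sum((s + 1) * p[g, s] for g in range(G) for s in range(S))
    return {
        "glszm.small_zone_emphasis": sum(
            Z[g, s] / (s + 1) ** 2 for g in range(G) for s in range(S)
        )
        / nz,
        "glszm.large_zone_emphasis": sum(
            Z[g, s] * (s + 1) ** 2 for g in range(G) for s in range(S)
        )
        / nz,
        "glszm.gray_level_non_uniformity": sum(
            Z[g, :].sum() ** 2 for g in range(G)
        )
        / nz,
        "glszm.zone_size_non_uniformity": sum(
            Z[:, s].sum() ** 2 for s in range(S)
        )
        / nz,
        "glszm.zone_percentage": nz / n_voxels,
        "glszm.low_gray_level_zone_emphasis": sum(
            Z[g, s] / (g + 1) ** 2 for g in range(G) for s in range(S)
        )
        / nz,
        "glszm.high_gray_level_zone_emphasis": sum(
            Z[g, s] * (g + 1) ** 2 for g in range(G) for s in range(S)
        )
        / nz,
        "glszm.small_zone_low_gray_level_emphasis": sum(
            Z[g, s] / ((g + 1) ** 2 * (s + 1) ** 2)
            for g in range(G)
            for s in range(S)
        )
        / nz,
        "glszm.small_zone_high_gray_level_emphasis": sum(
            Z[g, s] * (g + 1) ** 2 / (s + 1) ** 2
            for g in range(G)
            for s in range(S)
        )
        / nz,
        "glszm.large_zone_low_gray_level_emphasis": sum(
            Z[g, s] * (s + 1) ** 2 / (g + 1) ** 2
            for g in range(G)
            for s in range(S)
        )
        / nz,
        "glszm.large_zone_high_gray_level_emphasis": sum(
            Z[g, s] * (g + 1) ** 2 * (s + 1) ** 2
            for g in range(G)
            for s in range(S)
        )
        / nz,
        "glszm.gray_level_variance": sum(
            (g + 1 - mu_g) ** 2 * p[g, s] for g in range(G) for s in range(S)
        ),
        "glszm.zone_size_variance": sum(
            (s + 1 - mu_s) ** 2 * p[g, s] for g in range(G) for s in range(S)
        ),
    }


def formula_ngtdm(s, n):
    G = len(n)
    nvc = n.sum()
    p = n / nvc
    valid = [i for i in range(G) if n[i] > 0]
    ngp = len(valid)
    out = {}
    if ngp >= 2:
        out["ngtdm.contrast"] = (
            sum(
                p[i] * p[j] * (i - j) ** 2 for i in valid for j in valid
            )
            / (ngp * (ngp - 1))
            * (s.sum() / nvc)
        )
        out["ngtdm.complexity"] = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in valid
                for j in valid
            )
            / nvc
        )
        ssum = s.sum()
        out["ngtdm.strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in valid for j in valid) / ssum
            if ssum > 0
            else 0.0
        )
    else:
        out["ngtdm.contrast"] = 0.0
        out["ngtdm.complexity"] = 0.0
        out["ngtdm.strength"] = 0.0
    return out
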