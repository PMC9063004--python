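"""Feature statistics computed from the four texture matrices.

Each function returns a dict keyed like the registry (``glcm.contrast``,
...). Five features are flagged as volume-modified in the panel; where the
modified form differs from the plain IBSI definition both are computed and
the ``modified`` argument chooses which one lands under the panel key (the
other is available under ``<key>__unmodified`` / ``<key>__modified``):

* GLRLM gray-level and run-length non-uniformity — divided by the run
  count a second time (the "normalized" variants), removing the linear
  growth with ROI volume;
* NGTDM coarseness — multiplied by the number of contributing voxels
  (coarseness itself scales as 1/N);
* NGTDM busyness — divided by the number of contributing voxels (busyness
  scales as N);
* GLCM energy — the probability-based angular second moment is already
  volume-free, so the modified and plain forms coincide.

Degenerate statistics (single-level ROI: GLCM correlation, NGTDM
coarseness/busyness denominators) return NaN, the quiet missing-value
sentinel that the delta stage treats as missing.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .matrices import GLCMatrix, GLRLMatrix, GLSZMatrix, NGTDMatrix


def glcm_features(m: GLCMatrix) -> Dict[str, float]:
    """Eight co-occurrence statistics on the joint distribution."""
    P = m.P
    G = P.shape[0]
    i = np.arange(1, G + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float((px * i).sum())
    var_x = float((px * (i - mu_x) ** 2).sum())
    # symmetric P: marginals coincide
    if var_x > 0:
        correlation = float(((P * ii * jj).sum() - mu_x * mu_x) / var_x)
    else:
        correlation = float("nan")
    nz = P[P > 0]
    return {
        "glcm.contrast": float((P * (ii - jj) ** 2).sum()),
        "glcm.dissimilarity": float((P * np.abs(ii - jj)).sum()),
        "glcm.homogeneity": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "glcm.correlation": correlation,
        "glcm.energy": float((P**2).sum()),
        "glcm.variance": float((P * (ii - mu_x) ** 2).sum()),
        "glcm.entropy": float(-(nz * np.log2(nz)).sum()),
        "glcm.sum_average": float((P * (ii + jj)).sum()),
    }


def _rl_stats(M: np.ndarray):
    """Shared helper for run-length / size-zone tables: marginals and grids."""
    G, L = M.shape
    g = np.arange(1, G + 1, dtype=float)
    l = np.arange(1, L + 1, dtype=float)
    gg, ll = np.meshgrid(g, l, indexing="ij")
    return g, l, gg, ll, M.sum(axis=1), M.sum(axis=0)


def glrlm_features(m: GLRLMatrix, modified: bool = True) -> Dict[str, float]:
    """Thirteen run-length statistics on the direction-merged matrix.

    Run percentage is the run count over ``N_v × n_directions`` — each of
    the merged directions partitions the ROI into runs, so an ROI of
    isolated voxels gives exactly 1.
    """
    R = m.R
    nr = m.n_runs
    if nr < 1:
        raise ValueError("empty run-length matrix")
    g, l, gg, ll, r_g, r_l = _rl_stats(R)
    p = R / nr
    mu_g = float((p * gg).sum())
    mu_l = float((p * ll).sum())
    gln_plain = float((r_g**2).sum() / nr)
    rln_plain = float((r_l**2).sum() / nr)
    out = {
        "glrlm.short_run_emphasis": float((r_l / l**2).sum() / nr),
        "glrlm.long_run_emphasis": float((r_l * l**2).sum() / nr),
        "glrlm.gray_level_non_uniformity": gln_plain / nr if modified else gln_plain,
        "glrlm.run_length_non_uniformity": rln_plain / nr if modified else rln_plain,
        "glrlm.run_percentage": nr / (m.n_voxels * m.n_directions),
        "glrlm.low_gray_level_run_emphasis": float((r_g / g**2).sum() / nr),
        "glrlm.high_gray_level_run_emphasis": float((r_g * g**2).sum() / nr),
        "glrlm.short_run_low_gray_level_emphasis": float(
            (R / (gg**2 * ll**2)).sum() / nr
        ),
        "glrlm.short_run_high_gray_level_emphasis": float(
            (R * gg**2 / ll**2).sum() / nr
        ),
        "glrlm.long_run_low_gray_level_emphasis": float(
            (R * ll**2 / gg**2).sum() / nr
        ),
        "glrlm.long_run_high_gray_level_emphasis": float(
            (R * gg**2 * ll**2).sum() / nr
        ),
        "glrlm.gray_level_variance": float((p * (gg - mu_g) ** 2).sum()),
        "glrlm.run_length_variance": float((p * (ll - mu_l) ** 2).sum()),
    }
    out["glrlm.gray_level_non_uniformity__unmodified"] = gln_plain
    out["glrlm.run_length_non_uniformity__unmodified"] = rln_plain
    out["glrlm.gray_level_non_uniformity__modified"] = gln_plain / nr
    out["glrlm.run_length_non_uniformity__modified"] = rln_plain / nr
    return out


def glszm_features(m: GLSZMatrix) -> Dict[str, float]:
    """Thirteen size-zone statistics; zone percentage is ``n_zones / N_v``."""
    Z = m.Z
    nz = m.n_zones
    if nz < 1:
        raise ValueError("empty size-zone matrix")
    g, s, gg, ss, z_g, z_s = _rl_stats(Z)
    p = Z / nz
    mu_g = float((p * gg).sum())
    mu_s = float((p * ss).sum())
    return {
        "glszm.small_zone_emphasis": float((z_s / s**2).sum() / nz),
        "glszm.large_zone_emphasis": float((z_s * s**2).sum() / nz),
        "glszm.gray_level_non_uniformity": float((z_g**2).sum() / nz),
        "glszm.zone_size_non_uniformity": float((z_s**2).sum() / nz),
        "glszm.zone_percentage": nz / m.n_voxels,
        "glszm.low_gray_level_zone_emphasis": float((z_g / g**2).sum() / nz),
        "glszm.high_gray_level_zone_emphasis": float((z_g * g**2).sum() / nz),
        "glszm.small_zone_low_gray_level_emphasis": float(
            (Z / (gg**2 * ss**2)).sum() / nz
        ),
        "glszm.small_zone_high_gray_level_emphasis": float(
            (Z * gg**2 / ss**2).sum() / nz
        ),
        "glszm.large_zone_low_gray_level_emphasis": float(
            (Z * ss**2 / gg**2).sum() / nz
        ),
        "glszm.large_zone_high_gray_level_emphasis": float(
            (Z * gg**2 * ss**2).sum() / nz
        ),
        "glszm.gray_level_variance": float((p * (gg - mu_g) ** 2).sum()),
        "glszm.zone_size_variance": float((p * (ss - mu_s) ** 2).sum()),
    }


def ngtdm_features(m: NGTDMatrix, modified: bool = True) -> Dict[str, float]:
    """Five neighborhood gray-tone difference statistics.

    A uniform ROI has zero difference sums everywhere: contrast, complexity
    and strength are 0 by convention, while the coarseness and busyness
    denominators vanish and those features return the NaN sentinel.
    """
    s, n = m.s, m.n
    nvc = n.sum()
    if nvc == 0:
        raise ValueError("NGTDM has no contributing voxels")
    G = len(n)
    levels = np.arange(1, G + 1, dtype=float)
    p = n / nvc
    valid = n > 0
    ngp = int(valid.sum())
    iv = levels[valid]
    pv = p[valid]
    sv = s[valid]

    ps = float((p * s).sum())
    coarse_plain = 1.0 / ps if ps > 0 else float("nan")
    coarse_mod = coarse_plain * nvc if ps > 0 else float("nan")

    if ngp >= 2:
        di = iv[:, None] - iv[None, :]
        contrast = (
            float((pv[:, None] * pv[None, :] * di**2).sum())
            / (ngp * (ngp - 1))
            * float(s.sum() / nvc)
        )
        busy_denom = float(np.abs(iv[:, None] * pv[:, None] - iv[None, :] * pv[None, :]).sum())
        busy_plain = ps / busy_denom if busy_denom > 0 else float("nan")
        busy_mod = busy_plain / nvc if busy_denom > 0 else float("nan")
        complexity = float(
            (
                np.abs(di)
                * (pv[:, None] * sv[:, None] + pv[None, :] * sv[None, :])
                / (pv[:, None] + pv[None, :])
            ).sum()
        ) / nvc
        s_sum = float(s.sum())
        strength = (
            float(((pv[:, None] + pv[None, :]) * di**2).sum()) / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busy_plain = busy_mod = float("nan")
        complexity = 0.0
        strength = 0.0

    return {
        "ngtdm.coarseness": coarse_mod if modified else coarse_plain,
        "ngtdm.contrast": contrast,
        "ngtdm.busyness": busy_mod if modified else busy_plain,
        "ngtdm.complexity": complexity,
        "ngtdm.strength": strength,
        "ngtdm.coarseness__unmodified": coarse_plain,
        "ngtdm.busyness__unmodified": busy_plain,
        "ngtdm.coarseness__modified": coarse_mod,
        "ngtdm.busyness__modified": busy_mod,
    }
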