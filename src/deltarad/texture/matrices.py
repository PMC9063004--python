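"""Construction of the four texture matrices from a quantized ROI.

All builders treat level 0 as "outside the mask": such voxels never pair,
never extend a run, never join a zone and never count as neighbors. Voxel
conservation identities (GLCM probabilities sum to 1, GLSZM zone sizes sum
to the voxel count, NGTDM level counts sum to the number of voxels with at
least one in-mask neighbor) are asserted on every build.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
from scipy import ndimage

from .directions import DIRECTIONS_13, NEIGHBORS_26
from ..preprocess import QuantizedROI


def _offset_slices(shape, offset) -> Tuple[tuple, tuple]:
    """Slices (src, dst) such that src voxel v aligns with dst voxel v+offset."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


@dataclass
class GLCMatrix:
    """Symmetric co-occurrence probabilities, merged over directions."""

    P: np.ndarray
    displacement: int = 1
    n_directions: int = 13

    @property
    def n_levels(self) -> int:
        return self.P.shape[0]


@dataclass
class GLRLMatrix:
    """Counts of (gray level, run length), merged over directions."""

    R: np.ndarray  # G x L_max
    n_voxels: int
    n_directions: int = 13

    @property
    def n_runs(self) -> float:
        return float(self.R.sum())


@dataclass
class GLSZMatrix:
    """Counts of (gray level, zone size) for 26-connected zones."""

    Z: np.ndarray  # G x S_max
    n_voxels: int

    @property
    def n_zones(self) -> float:
        return float(self.Z.sum())


@dataclass
class NGTDMatrix:
    """Per-level neighborhood gray-tone difference sums.

    ``s[i]`` is the summed absolute difference between level ``i+1`` and the
    mean of the in-mask 26-neighbors, over the ``n[i]`` voxels at that level
    that have at least one in-mask neighbor.
    """

    s: np.ndarray
    n: np.ndarray
    n_voxels: int

    @property
    def n_levels(self) -> int:
        return len(self.n)

    @property
    def n_valid(self) -> int:
        return int(self.n.sum())

    @property
    def p(self) -> np.ndarray:
        return self.n / self.n.sum()


def build_glcm(
    roi: QuantizedROI,
    displacement: int = 1,
    directions: Optional[np.ndarray] = None,
) -> GLCMatrix:
    """Merged-3D symmetric GLCM at the given voxel displacement.

    Pairs are counted in both orientations for each direction, then the
    count table is normalized to probabilities.
    """
    if directions is None:
        directions = DIRECTIONS_13
    lv = roi.levels
    G = roi.n_levels
    counts = np.zeros((G, G), dtype=float)
    for d in directions:
        off = tuple(int(c) * displacement for c in d)
        src, dst = _offset_slices(lv.shape, off)
        a = lv[src].ravel()
        b = lv[dst].ravel()
        ok = (a > 0) & (b > 0)
        a, b = a[ok] - 1, b[ok] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("ROI has no in-mask voxel pair at this displacement")
    P = counts / total
    assert abs(P.sum() - 1.0) < 1e-9
    return GLCMatrix(P=P, displacement=displacement, n_directions=len(directions))


def _runs_along(levels: np.ndarray, direction) -> Tuple[np.ndarray, np.ndarray]:
    """Maximal same-level runs along one direction.

    Returns (levels, lengths) of every run of in-mask voxels. The grid is
    decomposed into scan lines parallel to ``direction``; a run breaks at a
    line boundary, a level change, or an out-of-mask voxel.
    """
    d = np.asarray(direction, dtype=int)
    m = int((d != 0).sum())  # step in the line parameter t per voxel
    coords = np.indices(levels.shape).reshape(3, -1)
    t = (coords * d[:, None]).sum(axis=0)
    # line key: invariant under v -> v + direction
    keys = coords * m - d[:, None] * t
    order = np.lexsort((t, keys[2], keys[1], keys[0]))
    seq = levels.ravel()[order]
    k = keys[:, order]
    newline = np.empty(seq.size, dtype=bool)
    newline[0] = True
    newline[1:] = (np.diff(k, axis=1) != 0).any(axis=0)
    is_break = newline.copy()
    is_break[1:] |= seq[1:] != seq[:-1]
    starts = np.flatnonzero(is_break)
    lengths = np.diff(np.append(starts, seq.size))
    run_levels = seq[starts]
    keep = run_levels > 0
    return run_levels[keep], lengths[keep]


def run_length_matrix(roi: QuantizedROI, direction) -> np.ndarray:
    """Run-length count matrix (G x L_max) for a single direction."""
    G = roi.n_levels
    lmax = max(roi.levels.shape)
    R = np.zeros((G, lmax), dtype=float)
    lv, ln = _runs_along(roi.levels, direction)
    np.add.at(R, (lv - 1, ln - 1), 1.0)
    return R


def build_glrlm(
    roi: QuantizedROI, directions: Optional[np.ndarray] = None
) -> GLRLMatrix:
    """Run-length matrix merged (summed) over the 13 directions."""
    if directions is None:
        directions = DIRECTIONS_13
    mats = [run_length_matrix(roi, d) for d in directions]
    R = np.sum(mats, axis=0)
    nv = roi.voxel_count
    # each direction's runs partition the in-mask voxels
    lengths = np.arange(1, R.shape[1] + 1)
    assert abs((R * lengths).sum() - nv * len(directions)) < 1e-6
    return GLRLMatrix(R=R, n_voxels=nv, n_directions=len(directions))


def build_glszm(roi: QuantizedROI) -> GLSZMatrix:
    """Size-zone matrix from 26-connected same-level zones."""
    G = roi.n_levels
    lv = roi.levels
    structure = np.ones((3, 3, 3), dtype=int)
    zones = []  # (level, size)
    for g in range(1, G + 1):
        binary = lv == g
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    smax = max(s for _, s in zones)
    Z = np.zeros((G, smax), dtype=float)
    for g, s in zones:
        Z[g - 1, s - 1] += 1.0
    sizes_axis = np.arange(1, smax + 1)
    assert abs((Z * sizes_axis).sum() - roi.voxel_count) < 1e-6
    return GLSZMatrix(Z=Z, n_voxels=roi.voxel_count)


def build_ngtdm(roi: QuantizedROI) -> NGTDMatrix:
    """Neighborhood gray-tone difference matrix over the 26-neighborhood.

    Only in-mask neighbors enter the neighborhood mean; voxels with no
    in-mask neighbor are excluded entirely, so a masked ROI edge cannot
    fabricate differences.
    """
    lv = roi.levels
    G = roi.n_levels
    inmask = lv > 0
    nbr_sum = np.zeros(lv.shape, dtype=float)
    nbr_cnt = np.zeros(lv.shape, dtype=float)
    for off in NEIGHBORS_26:
        src, dst = _offset_slices(lv.shape, tuple(int(c) for c in off))
        valid = inmask[dst]
        nbr_sum[src] += np.where(valid, lv[dst], 0)
        nbr_cnt[src] += valid
    sel = inmask & (nbr_cnt > 0)
    diff = np.zeros(lv.shape, dtype=float)
    diff[sel] = np.abs(lv[sel] - nbr_sum[sel] / nbr_cnt[sel])
    idx = lv[sel] - 1
    s = np.bincount(idx, weights=diff[sel], minlength=G)[:G]
    n = np.bincount(idx, minlength=G)[:G].astype(float)
    assert (s[n == 0] == 0).all()
    return NGTDMatrix(s=s, n=n, n_voxels=roi.voxel_count)
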