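"""Displacement vectors of the 3D 26-voxel neighborhood.

The 26 neighbors of a voxel come in 13 antipodal pairs; directional
matrices (GLCM, GLRLM) use one representative per pair and count both
orientations, which is equivalent to symmetrizing.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def _unique_directions() -> np.ndarray:
    dirs = []
    for off in product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        # keep the representative whose first nonzero component is positive
        first = next(c for c in off if c != 0)
        if first > 0:
            dirs.append(off)
    return np.array(dirs, dtype=int)


#: 13 unique directions (half of the 26-neighborhood, modulo sign).
DIRECTIONS_13 = _unique_directions()

#: All 26 neighbor offsets.
NEIGHBORS_26 = np.vstack([DIRECTIONS_13, -DIRECTIONS_13])

assert len(DIRECTIONS_13) == 13
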