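import numpy as np
import pytest

from deltarad.preprocess import QuantizedROI


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def random_quantized_roi(rng, max_side=4, max_levels=4, p_mask=0.8):
    """Small random ROI with a random mask, guaranteed at least one pair."""
    while True:
        shape = tuple(rng.integers(1, max_side + 1, size=3))
        G = int(rng.integers(2, max_levels + 1))
        levels = rng.integers(1, G + 1, size=shape)
        mask = rng.random(shape) < p_mask
        levels = np.where(mask, levels, 0)
        if (levels > 0).sum() < 2:
            continue
        # need one co-occurring in-mask pair somewhere in the 26-neighborhood
        pts = np.argwhere(levels > 0)
        diffs = np.abs(pts[:, None, :] - pts[None, :, :]).max(axis=2)
        if ((diffs == 1).any()):
            return QuantizedROI(levels, n_levels=G)


def quantized_from_levels(levels, n_levels=None):
    levels = np.asarray(levels)
    return QuantizedROI(levels, n_levels=int(n_levels or max(levels.max(), 2)))
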