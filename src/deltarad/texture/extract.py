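"""End-to-end feature extraction for one image/ROI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..preprocess import (
    DEFAULT_K_SIGMA,
    DEFAULT_N_LEVELS,
    MaskedROI,
    QuantizedROI,
    limit_dynamic_range,
    quantize_histogram_equalization,
)
from .matrices import build_glcm, build_glrlm, build_glszm, build_ngtdm
from .features import glcm_features, glrlm_features, glszm_features, ngtdm_features
from .registry import feature_keys


@dataclass
class TextureConfig:
    """Knobs for the normalization + texture stage.

    Defaults are the published settings: 64 gray levels, +/- 3 sigma
    dynamic-range limiting, displacement-one co-occurrence, and the
    volume-modified forms of the five flagged features.
    """

    n_levels: int = DEFAULT_N_LEVELS
    k_sigma: float = DEFAULT_K_SIGMA
    displacement: int = 1
    use_modified: bool = True
    include_twins: bool = False


def extract_all(roi: MaskedROI, config: TextureConfig | None = None) -> pd.Series:
    """Compute the 39-feature vector for one masked image.

    Chain: dynamic-range limiting -> histogram-equalization quantization ->
    GLCM / GLRLM / GLSZM / NGTDM -> named statistics, returned as a Series
    in panel order. With ``config.include_twins`` the alternate
    (modified/unmodified) forms of the flagged features are appended under
    ``<key>__modified`` / ``<key>__unmodified``.
    """
    cfg = config or TextureConfig()
    quant = quantize_histogram_equalization(
        limit_dynamic_range(roi, cfg.k_sigma), cfg.n_levels
    )
    return extract_from_quantized(quant, cfg)


def _crop_to_mask(quant: QuantizedROI) -> QuantizedROI:
    """Restrict to the mask bounding box; texture statistics are unchanged."""
    idx = np.nonzero(quant.levels > 0)
    slices = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return QuantizedROI(quant.levels[slices], quant.n_levels, quant.voxel_size)


def extract_from_quantized(
    quant: QuantizedROI, config: TextureConfig | None = None
) -> pd.Series:
    """Feature vector from an already-quantized ROI."""
    cfg = config or TextureConfig()
    quant = _crop_to_mask(quant)
    values = {}
    values.update(glcm_features(build_glcm(quant, displacement=cfg.displacement)))
    values.update(glrlm_features(build_glrlm(quant), modified=cfg.use_modified))
    values.update(glszm_features(build_glszm(quant)))
    values.update(ngtdm_features(build_ngtdm(quant), modified=cfg.use_modified))
    keys = feature_keys()
    if cfg.include_twins:
        keys = keys + sorted(k for k in values if "__" in k)
    vec = pd.Series({k: values[k] for k in keys}, dtype=float)[keys]
    assert len(vec) >= 39
    return vec
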