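"""Extract the 39-feature texture panel from one masked image.

Builds a small correlated random field inside an ellipsoidal mask (a
stand-in for a GTV on a setup image), runs the normalization chain
(+/- 3 sigma clip, 64-level histogram equalization) and the four 3D
texture matrices, and prints a few of the named features.
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from deltarad import MaskedROI, TextureConfig, extract_all

rng = np.random.default_rng(0)
field = gaussian_filter(rng.standard_normal((32, 32, 32)), sigma=1.2)
grids = np.indices((32, 32, 32)) - 15.5
mask = ((grids[0] / 8) ** 2 + (grids[1] / 7) ** 2 + (grids[2] / 6) ** 2) <= 1

vec = extract_all(MaskedROI(field, mask), TextureConfig())
print(f"ROI: {int(mask.sum())} voxels, 64 gray levels, 39 features\n")
for key in ["glcm.contrast", "glcm.sum_average", "glrlm.run_percentage",
            "glszm.large_zone_low_gray_level_emphasis", "ngtdm.busyness"]:
    print(f"{key:45s} {vec[key]:10.4f}")
print("\nThe smooth, spatially correlated field keeps GLCM contrast well")
print("below the ~680 of an uncorrelated 64-level field; rerunning with")
print("a sharper field (smaller smoothing sigma) raises contrast.")
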