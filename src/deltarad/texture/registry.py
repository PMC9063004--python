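"""The 39-feature panel: names, IBSI codes, and volume-modification flags.

Features are keyed ``<class>.<snake_case_name>``; the display name and IBSI
feature code follow the published panel (codes are metadata only — two
matrix classes print the same code for their gray-level and size/length
variance pair, so codes are not unique keys). Features flagged ``modified``
are reported in a volume-decoupled form by default; their plain IBSI twins
remain available (see :mod:`deltarad.texture.features`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional


@dataclass(frozen=True)
class FeatureInfo:
    key: str
    matrix_class: str
    display_name: str
    ibsi_code: str
    modified: bool = False


def _f(cls: str, name: str, code: str, modified: bool = False) -> FeatureInfo:
    key = f"{cls.lower()}.{name.lower().replace(' ', '_').replace('-', '_')}"
    return FeatureInfo(key, cls, name, code, modified)


#: Panel order: 8 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM.
FEATURES: List[FeatureInfo] = [
    _f("GLCM", "Contrast", "ACUI"),
    _f("GLCM", "Dissimilarity", "8S9J"),
    _f("GLCM", "Homogeneity", "IB1Z"),
    _f("GLCM", "Correlation", "NI2N"),
    _f("GLCM", "Energy", "8ZQL", modified=True),
    _f("GLCM", "Variance", "UR99"),
    _f("GLCM", "Entropy", "TU9B"),
    _f("GLCM", "Sum average", "ZGXS"),
    _f("GLRLM", "Short run emphasis", "220V"),
    _f("GLRLM", "Long run emphasis", "W4KF"),
    _f("GLRLM", "Gray-level non-uniformity", "R5YN", modified=True),
    _f("GLRLM", "Run length non-uniformity", "W92Y", modified=True),
    _f("GLRLM", "Run percentage", "9ZK5"),
    _f("GLRLM", "Low gray-level run emphasis", "V3SW"),
    _f("GLRLM", "High gray-level run emphasis", "G3QZ"),
    _f("GLRLM", "Short run low gray-level emphasis", "HTZT"),
    _f("GLRLM", "Short run high gray-level emphasis", "GD3A"),
    _f("GLRLM", "Long run low gray-level emphasis", "IVPO"),
    _f("GLRLM", "Long run high gray-level emphasis", "3KUM"),
    _f("GLRLM", "Gray-level variance", "8CE5"),
    _f("GLRLM", "Run length variance", "8CE5"),
    _f("GLSZM", "Small zone emphasis", "5QRC"),
    _f("GLSZM", "Large zone emphasis", "48P8"),
    _f("GLSZM", "Gray-level non-uniformity", "JNSA"),
    _f("GLSZM", "Zone-size non-uniformity", "4JP3"),
    _f("GLSZM", "Zone percentage", "P30P"),
    _f("GLSZM", "Low gray-level zone emphasis", "XMSY"),
    _f("GLSZM", "High gray-level zone emphasis", "5GN9"),
    _f("GLSZM", "Small zone low gray-level emphasis", "5RAI"),
    _f("GLSZM", "Small zone high gray-level emphasis", "HW1V"),
    _f("GLSZM", "Large zone low gray-level emphasis", "YH51"),
    _f("GLSZM", "Large zone high gray-level emphasis", "J17V"),
    _f("GLSZM", "Gray-level variance", "BYLV"),
    _f("GLSZM", "Zone-size variance", "BYLV"),
    _f("NGTDM", "Coarseness", "QCDE", modified=True),
    _f("NGTDM", "Contrast", "65HE"),
    _f("NGTDM", "Busyness", "NQ30", modified=True),
    _f("NGTDM", "Complexity", "HDEZ"),
    _f("NGTDM", "Strength", "1X9X"),
]

assert len(FEATURES) == 39


def feature_keys() -> List[str]:
    """The 39 feature keys in panel order."""
    return [f.key for f in FEATURES]


def feature_by_key(key: str) -> Optional[FeatureInfo]:
    for f in FEATURES:
        if f.key == key:
            return f
    return None
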