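"""Delta features: change of each texture statistic against baseline.

A delta feature is the difference between the value on the pre-treatment
(fraction 1) setup image and the value on the image assigned to a dose bin,

    delta = f_pre - f_post,

so a feature that *increases* under treatment has a negative delta (and a
negative percent change). The percent-change form, 100 * (f_pre - f_post)
/ f_pre, is reported for summaries; the raw difference feeds the models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import pandas as pd

from .schedule import DoseBinAssignment

log = logging.getLogger(__name__)

BIN_TAGS = ("BED20", "BED40")


def delta_feature(f_pre: float, f_post: float) -> float:
    """Raw delta, ``f_pre - f_post``; NaN if either value is missing."""
    if math.isnan(f_pre) or math.isnan(f_post):
        return float("nan")
    return f_pre - f_post


def percent_change(f_pre: float, f_post: float) -> float:
    """Percent change from baseline, ``100 * (f_pre - f_post) / f_pre``.

    Undefined (NaN, logged) when the baseline value is zero.
    """
    if math.isnan(f_pre) or math.isnan(f_post):
        return float("nan")
    if f_pre == 0:
        log.warning("percent change undefined: baseline value is 0")
        return float("nan")
    return 100.0 * (f_pre - f_post) / f_pre


@dataclass
class DeltaFeatureTable:
    """Patients x features delta table for one dose bin.

    ``data`` is indexed by patient_id with one column per feature;
    ``labels`` maps patient_id -> RS/NR. Patients whose bin image is
    missing are absent (never zero-filled).
    """

    bin_tag: str
    data: pd.DataFrame
    labels: pd.Series
    convention: str = "difference"  # or "percent_change"

    def __post_init__(self) -> None:
        if self.bin_tag not in BIN_TAGS:
            raise ValueError(f"bin_tag must be one of {BIN_TAGS}")
        self.labels = self.labels.loc[self.data.index]

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def dropna(self) -> "DeltaFeatureTable":
        """Listwise deletion: drop patients with any missing feature."""
        kept = self.data.dropna(axis=0)
        return DeltaFeatureTable(self.bin_tag, kept, self.labels.loc[kept.index], self.convention)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "response", self.labels)
        out.to_csv(path, index_label="patient_id")


def build_delta_table(
    features: pd.DataFrame,
    assignments: Mapping[str, DoseBinAssignment],
    labels: Mapping[str, str],
    bin_tag: str,
    convention: str = "difference",
) -> DeltaFeatureTable:
    """Pair each patient's baseline vector with the bin's assigned image.

    Parameters
    ----------
    features : DataFrame
        Tidy per-image feature table with columns ``patient_id``,
        ``fraction`` (1-based) and one column per feature.
    assignments : mapping
        patient_id -> DoseBinAssignment (from :func:`assign_dose_bins`).
    labels : mapping
        patient_id -> RS | NR.
    bin_tag : str
        "BED20" or "BED40".
    convention : str
        "difference" (default, feeds the models) or "percent_change".

    Patients whose assigned image is missing, or whose bin is unreachable
    or out-of-window, are dropped with a warning.
    """
    if bin_tag not in BIN_TAGS:
        raise ValueError(f"bin_tag must be one of {BIN_TAGS}")
    feat_cols = [c for c in features.columns if c not in ("patient_id", "fraction")]
    indexed = features.set_index(["patient_id", "fraction"])[feat_cols]
    rows: Dict[str, pd.Series] = {}
    kept_labels: Dict[str, str] = {}
    for pid, asg in assignments.items():
        if bin_tag == "BED20":
            idx = asg.bed20_image_index
            if idx is not None and not asg.bed20_in_window:
                log.warning("%s: BED20 crossing falls outside 20-30 Gy; dropped", pid)
                idx = None
        else:
            idx = asg.bed40_image_index
        if idx is None:
            log.warning("%s: %s bin unreachable; dropped", pid, bin_tag)
            continue
        try:
            pre = indexed.loc[(pid, 1)]
            post = indexed.loc[(pid, idx)]
        except KeyError:
            log.warning("%s: missing image for fraction 1 or %d; dropped", pid, idx)
            continue
        if convention == "difference":
            row = pre - post
        elif convention == "percent_change":
            row = pd.Series(
                {c: percent_change(pre[c], post[c]) for c in feat_cols}, dtype=float
            )
        else:
            raise ValueError(f"unknown convention {convention!r}")
        rows[pid] = row
        kept_labels[pid] = labels[pid]
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = "patient_id"
    return DeltaFeatureTable(
        bin_tag=bin_tag,
        data=data,
        labels=pd.Series(kept_labels, name="response"),
        convention=convention,
    )
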