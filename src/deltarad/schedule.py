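"""Biologically effective dose (BED) bookkeeping and dose-bin assignment.

Stereotactic schedules with different fraction sizes are put on a common
dose scale with the linear-quadratic BED,

    BED = n * d * (1 + d / (alpha/beta)),

where ``n`` is the number of fractions, ``d`` the physical dose per fraction
in Gy, and ``alpha/beta`` the tissue fractionation-sensitivity ratio (10 Gy
for tumor). Dividing the total BED by the number of fractions gives a
BED-per-fraction rate, which maps each patient's daily setup images onto two
delta-feature windows:

* ``BED20`` — the first setup image acquired after a cumulative delivered
  BED of 20–30 Gy, and
* ``BED40`` — the first setup image acquired after a cumulative BED of
  40 Gy or more.

A setup image is acquired *before* that day's delivery, so dose delivered
through fraction ``k`` is first visible on the image of fraction ``k + 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

DEFAULT_ALPHA_BETA = 10.0

#: Cumulative-BED window (Gy) defining each bin: (threshold, upper bound).
BED20_WINDOW = (20.0, 30.0)
BED40_THRESHOLD = 40.0


def compute_bed(
    n_fractions: int,
    dose_per_fraction: float,
    alpha_beta: float = DEFAULT_ALPHA_BETA,
) -> float:
    """Total BED in Gy for ``n`` equal fractions of ``d`` Gy.

    Parameters
    ----------
    n_fractions : int
        Number of delivered fractions (>= 1).
    dose_per_fraction : float
        Physical dose per fraction in Gy (> 0).
    alpha_beta : float
        Alpha/beta ratio in Gy; 10 Gy is the conventional tumor value.
    """
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    if dose_per_fraction <= 0:
        raise ValueError(f"dose_per_fraction must be > 0, got {dose_per_fraction}")
    if alpha_beta <= 0:
        raise ValueError(f"alpha_beta must be > 0, got {alpha_beta}")
    return n_fractions * dose_per_fraction * (1.0 + dose_per_fraction / alpha_beta)


def bed_per_fraction(total_bed: float, n_fractions: int) -> float:
    """BED delivered per fraction: total BED divided by the fraction count."""
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    return total_bed / n_fractions


@dataclass(frozen=True)
class TreatmentSchedule:
    """One patient's fractionation on the BED scale.

    Either the physical prescription (``n_fractions`` + ``dose_per_fraction``)
    or the BED description (``total_bed`` + ``bed_per_fraction`` or
    ``n_fractions``) is enough to construct it; use the classmethods.
    """

    patient_id: str
    n_fractions: int
    total_bed: float
    bed_per_fraction: float
    dose_per_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.bed_per_fraction <= 0 or self.total_bed <= 0:
            raise ValueError("BED quantities must be positive")

    @classmethod
    def from_physical(
        cls,
        patient_id: str,
        n_fractions: int,
        dose_per_fraction: float,
        alpha_beta: float = DEFAULT_ALPHA_BETA,
    ) -> "TreatmentSchedule":
        total = compute_bed(n_fractions, dose_per_fraction, alpha_beta)
        return cls(
            patient_id=str(patient_id),
            n_fractions=n_fractions,
            total_bed=total,
            bed_per_fraction=bed_per_fraction(total, n_fractions),
            dose_per_fraction=dose_per_fraction,
        )

    @classmethod
    def from_bed(
        cls,
        patient_id: str,
        total_bed: float,
        bed_per_fx: Optional[float] = None,
        n_fractions: Optional[int] = None,
    ) -> "TreatmentSchedule":
        """Build from total BED plus either the per-fraction BED or ``n``.

        When only the per-fraction rate is given, ``n`` is recovered as
        ``round(total_bed / bed_per_fx)``; the ratio must sit within 0.1 of
        an integer. Published per-fraction rates are rounded to 0.1 Gy, so
        the product ``n * bed_per_fx`` may miss ``total_bed`` by a few tenths
        of a Gy — the printed values are kept verbatim.
        """
        if n_fractions is None:
            if bed_per_fx is None:
                raise ValueError("need bed_per_fx or n_fractions")
            ratio = total_bed / bed_per_fx
            n_fractions = round(ratio)
            if n_fractions < 1 or abs(ratio - n_fractions) > 0.1:
                raise ValueError(
                    f"total_bed / bed_per_fx = {ratio:.3f} is not near an integer"
                )
        if bed_per_fx is None:
            bed_per_fx = bed_per_fraction(total_bed, n_fractions)
        return cls(
            patient_id=str(patient_id),
            n_fractions=n_fractions,
            total_bed=total_bed,
            bed_per_fraction=bed_per_fx,
        )


@dataclass(frozen=True)
class DoseBinAssignment:
    """Which setup image pairs with fraction 1 for each delta window.

    Indices are 1-based fraction numbers. An unreachable bin is ``None``
    (the patient is excluded from that bin, not an error).
    ``bed20_in_window`` is False when the cumulative BED at the first
    crossing of 20 Gy overshoots the 30 Gy upper bound.
    """

    patient_id: str
    bed20_image_index: Optional[int]
    bed40_image_index: Optional[int]
    bed20_in_window: bool = True
    bed_before_bed20: Optional[float] = None
    bed_before_bed40: Optional[float] = None

    @property
    def bed20_pair(self) -> Optional[str]:
        if self.bed20_image_index is None:
            return None
        return f"Fx1-Fx{self.bed20_image_index}"

    @property
    def bed40_pair(self) -> Optional[str]:
        if self.bed40_image_index is None:
            return None
        return f"Fx1-Fx{self.bed40_image_index}"


def assign_dose_bins(schedule: TreatmentSchedule) -> DoseBinAssignment:
    """Map a schedule onto the BED20 and BED40 setup images.

    The BED20 image is the setup image of fraction ``k + 1`` where ``k`` is
    the smallest fraction count whose cumulative BED reaches 20 Gy; the bin
    is flagged out-of-window if that cumulative BED exceeds 30 Gy. The BED40
    image is defined the same way with a 40 Gy threshold and no upper bound.
    """
    rate = schedule.bed_per_fraction
    n = schedule.n_fractions
    low, high = BED20_WINDOW

    def first_crossing(threshold: float) -> Optional[int]:
        k = math.ceil(threshold / rate - 1e-9)
        k = max(k, 1)
        # image k+1 must exist
        if k + 1 > n:
            return None
        return k

    k20 = first_crossing(low)
    k40 = first_crossing(BED40_THRESHOLD)
    in_window = True
    if k20 is not None:
        in_window = k20 * rate <= high + 1e-9
    return DoseBinAssignment(
        patient_id=schedule.patient_id,
        bed20_image_index=None if k20 is None else k20 + 1,
        bed40_image_index=None if k40 is None else k40 + 1,
        bed20_in_window=in_window,
        bed_before_bed20=None if k20 is None else k20 * rate,
        bed_before_bed40=None if k40 is None else k40 * rate,
    )


def read_schedule_csv(path) -> pd.DataFrame:
    """Read a cohort schedule table.

    Expected columns: ``patient_id``, ``response`` (RS/NR) and one of the
    dose descriptions — ``n_fractions`` + ``dose_per_fraction_gy``, or
    ``total_bed_gy`` + (``bed_per_fraction_gy`` or ``n_fractions``).
    Returns the table with a ``schedule`` column of TreatmentSchedule objects.
    """
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("schedule table needs a patient_id column")
    schedules = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if "total_bed_gy" in df.columns and not pd.isna(row.get("total_bed_gy")):
            schedules.append(
                TreatmentSchedule.from_bed(
                    pid,
                    float(row["total_bed_gy"]),
                    bed_per_fx=(
                        float(row["bed_per_fraction_gy"])
                        if "bed_per_fraction_gy" in df.columns
                        else None
                    ),
                    n_fractions=(
                        int(row["n_fractions"]) if "n_fractions" in df.columns else None
                    ),
                )
            )
        else:
            schedules.append(
                TreatmentSchedule.from_physical(
                    pid, int(row["n_fractions"]), float(row["dose_per_fraction_gy"])
                )
            )
    out = df.copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out["schedule"] = schedules
    return out


def reference_cohort() -> pd.DataFrame:
    """The packaged 30-patient pancreatic SBRT cohort schedule.

    Columns include the published per-patient response label (11 RS, 19 NR),
    total BED, BED per fraction, and the expected Fx pairs for each bin.
    """
    with resources.files("deltarad.data").joinpath("cohort_schedules.csv").open() as fh:
        return read_schedule_csv(fh)
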