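"""Synthetic longitudinal cohorts with a controllable texture-drift signal.

Each synthetic patient is an ellipsoidal "tumor" ROI on a 32^3 grid filled
with a correlated Gaussian random field (white noise convolved with a
Gaussian kernel; the kernel width sets the spatial autocorrelation length).
Fraction volumes share the patient's underlying noise field, so with all
stochastic perturbations switched off (zero voxel noise, zero smoothness
jitter, zero effect) every fraction image is identical and all delta
features vanish.

The acquisition noise has two components, mirroring how daily MR setup
images actually vary: i.i.d. voxel noise, and a coherent day-to-day
*smoothness jitter* — each acquisition's autocorrelation length is drawn
around the patient's base value. The jitter moves all texture features
together (one shared mode), the way scanner blur and repositioning shift a
whole radiomic panel coherently, while the voxel noise perturbs features
more independently.

The treatment-response signal is a *texture* drift, not an intensity
drift: on the setup image assigned to the effect bin (BED20 by default),
responders' fields are smoothed with a longer correlation length
(``base_corr_sigma * (1 + effect_size)``), which shifts the spatial
correlation structure that all four matrix families measure while leaving
the intensity histogram essentially unchanged — histogram-equalized
quantization discards first-order differences anyway. Non-responders never
drift, and no class drifts at the BED40 image, so a well-behaved pipeline
should separate classes at BED20 and not at BED40.

Fractionation schedules are drawn from the 30-patient reference cohort mix
(BED/fraction in {11.0, 11.9, 12.3, 14.4, 20.0, 26.4} Gy, five fractions);
at the default size of 30 patients with an 11/19 responder split the
reference rows are used verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .schedule import (
    DoseBinAssignment,
    TreatmentSchedule,
    assign_dose_bins,
    reference_cohort,
)


@dataclass
class CohortSpec:
    """Study-condition knobs for the generator.

    Defaults emulate the reference cohort: 30 patients, 11 responders / 19
    non-responders, five-fraction schedules with the published BED/fraction
    mix, GTV-sized ellipsoidal ROIs of roughly 500–3000 voxels.
    """

    n_patients: int = 30
    n_responders: int = 11
    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    roi_semiaxis_range: Tuple[float, float] = (5.0, 9.0)  # voxels
    base_corr_sigma: float = 1.0  # autocorrelation length, voxels
    noise_sd: float = 0.05  # i.i.d. voxel noise, relative to field SD
    smoothness_jitter_sd: float = 0.05  # day-to-day correlation-length jitter
    effect_size: float = 0.5  # relative correlation-length increase
    effect_bin: str = "BED20"
    effect_class: str = "RS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_responders <= self.n_patients:
            raise ValueError("class counts must sum to n_patients")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class SyntheticPatient:
    patient_id: str
    label: str
    schedule: TreatmentSchedule
    assignment: DoseBinAssignment
    volumes: List[np.ndarray]  # one per fraction, index 0 = fraction 1
    masks: List[np.ndarray]

    @property
    def n_fractions(self) -> int:
        return len(self.volumes)


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    patients: List[SyntheticPatient]

    @property
    def labels(self) -> Dict[str, str]:
        return {p.patient_id: p.label for p in self.patients}

    @property
    def schedules(self) -> Dict[str, TreatmentSchedule]:
        return {p.patient_id: p.schedule for p in self.patients}

    @property
    def assignments(self) -> Dict[str, DoseBinAssignment]:
        return {p.patient_id: p.assignment for p in self.patients}


def _ellipsoid_mask(shape, semiaxes, rng) -> np.ndarray:
    center = np.array(shape) / 2.0 - 0.5
    grids = np.indices(shape).astype(float)
    r2 = sum(
        ((grids[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3)
    )
    mask = r2 <= 1.0
    if mask.sum() < 8:
        raise ValueError("ROI smaller than 8 voxels")
    return mask


def generate_patient(
    spec: CohortSpec,
    patient_id: str,
    label: str,
    schedule: TreatmentSchedule,
    seed: int,
) -> SyntheticPatient:
    """One patient's longitudinal volumes, masks and schedule.

    Deterministic in ``seed``. The effect-class patients get a longer
    autocorrelation length on the setup image their schedule assigns to the
    effect bin; every fraction receives independent acquisition noise.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.roi_semiaxis_range
    semiaxes = rng.uniform(lo, hi, size=3)
    mask = _ellipsoid_mask(spec.grid_shape, semiaxes, rng)
    base_field = rng.standard_normal(spec.grid_shape)
    assignment = assign_dose_bins(schedule)
    effect_index = (
        assignment.bed20_image_index
        if spec.effect_bin == "BED20"
        else assignment.bed40_image_index
    )
    volumes = []
    for fx in range(1, schedule.n_fractions + 1):
        # every acquisition carries a coherent day-to-day blur jitter on top
        # of the patient's base autocorrelation length
        jitter = 1.0 + spec.smoothness_jitter_sd * rng.standard_normal()
        sigma = spec.base_corr_sigma * max(jitter, 0.2)
        if label == spec.effect_class and fx == effect_index:
            sigma *= 1.0 + spec.effect_size
        vol = gaussian_filter(base_field, sigma=sigma, mode="nearest")
        sd = vol[mask].std()
        vol = vol + spec.noise_sd * sd * rng.standard_normal(spec.grid_shape)
        volumes.append(vol)
    return SyntheticPatient(
        patient_id=patient_id,
        label=label,
        schedule=schedule,
        assignment=assignment,
        volumes=volumes,
        masks=[mask.copy() for _ in volumes],
    )


def _cohort_rows(spec: CohortSpec, rng) -> List[Tuple[str, float, float]]:
    """(label, total_bed, bed_per_fx) per patient, mirroring the reference mix."""
    ref = reference_cohort()
    if spec.n_patients == len(ref) and spec.n_responders == int((ref["response"] == "RS").sum()):
        return [
            (r.response, float(r.total_bed_gy), float(r.bed_per_fraction_gy))
            for r in ref.itertuples()
        ]
    pool = list(zip(ref["total_bed_gy"].astype(float), ref["bed_per_fraction_gy"].astype(float)))
    labels = ["RS"] * spec.n_responders + ["NR"] * (spec.n_patients - spec.n_responders)
    rows = []
    for lab in labels:
        tb, bfx = pool[rng.integers(len(pool))]
        rows.append((lab, tb, bfx))
    return rows


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Full deterministic cohort; per-patient streams spawn from ``spec.seed``."""
    root_ss = np.random.SeedSequence(spec.seed)
    mix_rng = np.random.default_rng(root_ss.spawn(1)[0])
    rows = _cohort_rows(spec, mix_rng)
    child_seeds = root_ss.spawn(len(rows))
    patients = []
    for i, ((label, total_bed, bed_fx), ss) in enumerate(zip(rows, child_seeds), start=1):
        pid = f"P{i:02d}"
        schedule = TreatmentSchedule.from_bed(pid, total_bed, bed_per_fx=bed_fx)
        patients.append(
            generate_patient(spec, pid, label, schedule, seed=ss.generate_state(1)[0] % (2**31))
        )
    return SyntheticCohort(spec=spec, patients=patients)


def write_cohort(cohort: SyntheticCohort, root: Path) -> Path:
    """Write the on-disk layout the pipeline consumes.

    One directory per patient with ``fx{k}_image.nii.gz`` and
    ``fx{k}_mask.nii.gz``, plus cohort-level ``schedule.csv`` and
    ``labels.csv``.
    """
    import nibabel as nib

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    affine = np.diag([1.5, 1.5, 3.0, 1.0])  # native anisotropic grid, mm
    sched_rows = []
    label_rows = []
    for p in cohort.patients:
        pdir = root / p.patient_id
        pdir.mkdir(exist_ok=True)
        for k, (vol, mask) in enumerate(zip(p.volumes, p.masks), start=1):
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), pdir / f"fx{k}_image.nii.gz")
            nib.save(
                nib.Nifti1Image(mask.astype(np.uint8), affine), pdir / f"fx{k}_mask.nii.gz"
            )
        sched_rows.append(
            {
                "patient_id": p.patient_id,
                "n_fractions": p.schedule.n_fractions,
                "total_bed_gy": p.schedule.total_bed,
                "bed_per_fraction_gy": p.schedule.bed_per_fraction,
                "response": p.label,
            }
        )
        label_rows.append({"patient_id": p.patient_id, "response": p.label})
    pd.DataFrame(sched_rows).to_csv(root / "schedule.csv", index=False)
    pd.DataFrame(label_rows).to_csv(root / "labels.csv", index=False)
    return root
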