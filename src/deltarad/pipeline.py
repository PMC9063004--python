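"""End-to-end orchestration: cohort in, ranked features and AUC reports out.

The pipeline chains schedule -> preprocessing -> texture -> delta ->
random-forest ranking -> bootstrapped validation for the BED20 and BED40
bins, either from an on-disk cohort layout (one directory per patient with
``fx{k}_image.nii.gz`` / ``fx{k}_mask.nii.gz`` plus ``schedule.csv`` and
``labels.csv``) or from an in-memory synthetic cohort. A JSON manifest
records the configuration, seed, package version and per-stage row counts
so every report is regenerable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delta import BIN_TAGS, DeltaFeatureTable, build_delta_table
from .preprocess import MaskedROI
from .schedule import DoseBinAssignment, assign_dose_bins, read_schedule_csv
from .selection import ImportanceRanking, rank_by_gini, select_top_k
from .synthetic import SyntheticCohort
from .texture import TextureConfig, extract_all
from .validation import ValidationReport, bootstrap_validate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the published analysis settings."""

    cohort_root: Optional[str] = None
    output_dir: Optional[str] = None
    n_levels: int = 64
    k_sigma: float = 3.0
    use_modified: bool = True
    delta_convention: str = "difference"
    n_trees: int = 500
    n_iter: int = 1000
    train_fraction: float = 2.0 / 3.0
    top_k: int = 2
    propagate_first_mask: bool = False
    seed: int = 0

    def texture_config(self) -> TextureConfig:
        return TextureConfig(
            n_levels=self.n_levels, k_sigma=self.k_sigma, use_modified=self.use_modified
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    features: pd.DataFrame  # tidy: patient_id, fraction, 39 columns
    delta_tables: Dict[str, DeltaFeatureTable]
    rankings: Dict[str, ImportanceRanking]
    selected: Dict[str, List[str]]
    reports: Dict[str, ValidationReport]
    manifest: dict


def _stage_seeds(seed: int) -> Dict[str, int]:
    """Deterministic substreams for each stochastic stage."""
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(2 * len(BIN_TAGS))
    out = {}
    for i, tag in enumerate(BIN_TAGS):
        out[f"rf_{tag}"] = int(kids[2 * i].generate_state(1)[0] % (2**31))
        out[f"boot_{tag}"] = int(kids[2 * i + 1].generate_state(1)[0] % (2**31))
    return out


def extract_cohort_features(
    patients: dict, config: PipelineConfig
) -> pd.DataFrame:
    """Extract the 39-feature vector for every needed (patient, fraction).

    ``patients`` maps patient_id to a dict with keys ``assignment`` and
    ``images`` (fraction index -> (volume, mask)). Only fraction 1 and the
    bin-assigned fractions are extracted. Patients failing extraction are
    dropped with a logged reason.
    """
    tex_cfg = config.texture_config()
    rows = []
    for pid, entry in sorted(patients.items()):
        asg: DoseBinAssignment = entry["assignment"]
        needed = {1}
        for idx in (asg.bed20_image_index, asg.bed40_image_index):
            if idx is not None:
                needed.add(idx)
        for fx in sorted(needed):
            if fx not in entry["images"]:
                log.warning("%s: no image for fraction %d", pid, fx)
                continue
            vol, mask = entry["images"][fx]
            try:
                vec = extract_all(MaskedROI(vol, mask), tex_cfg)
            except (ValueError, KeyError) as exc:
                log.warning("%s fx%d: extraction failed (%s); skipped", pid, fx, exc)
                continue
            row = {"patient_id": pid, "fraction": fx}
            row.update(vec.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(
    features: pd.DataFrame,
    assignments: Dict[str, DoseBinAssignment],
    labels: Dict[str, str],
    config: PipelineConfig,
) -> PipelineResult:
    """Delta tables, Gini rankings, top-k selection and bootstrap reports."""
    seeds = _stage_seeds(config.seed)
    delta_tables, rankings, selected, reports = {}, {}, {}, {}
    for tag in BIN_TAGS:
        table = build_delta_table(
            features, assignments, labels, tag, convention=config.delta_convention
        )
        delta_tables[tag] = table
        ranking = rank_by_gini(table, n_trees=config.n_trees, seed=seeds[f"rf_{tag}"])
        rankings[tag] = ranking
        chosen = select_top_k(ranking, k=config.top_k)
        selected[tag] = chosen
        reports[tag] = bootstrap_validate(
            table,
            chosen,
            n_iter=config.n_iter,
            train_fraction=config.train_fraction,
            seed=seeds[f"boot_{tag}"],
        )
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "n_feature_rows": int(len(features)),
        "rows_per_bin": {t: delta_tables[t].n_patients for t in BIN_TAGS},
        "selected_features": selected,
        "reports": {t: reports[t].summary() for t in BIN_TAGS},
    }
    return PipelineResult(
        config=config,
        features=features,
        delta_tables=delta_tables,
        rankings=rankings,
        selected=selected,
        reports=reports,
        manifest=manifest,
    )


def run_cohort(cohort: SyntheticCohort, config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full pipeline on an in-memory synthetic cohort."""
    config = config or PipelineConfig()
    patients = {
        p.patient_id: {
            "assignment": p.assignment,
            "images": {
                k + 1: (p.volumes[k], p.masks[k]) for k in range(p.n_fractions)
            },
        }
        for p in cohort.patients
    }
    features = extract_cohort_features(patients, config)
    result = analyze_cohort(features, cohort.assignments, cohort.labels, config)
    if config.output_dir:
        write_artifacts(result, Path(config.output_dir))
    return result


def load_cohort_dir(root: Path, config: PipelineConfig) -> tuple:
    """Read the on-disk cohort layout into pipeline inputs."""
    import nibabel as nib

    root = Path(root)
    sched_df = read_schedule_csv(root / "schedule.csv")
    labels_df = pd.read_csv(root / "labels.csv", dtype={"patient_id": str})
    labels = dict(zip(labels_df["patient_id"], labels_df["response"]))
    patients = {}
    assignments = {}
    for row in sched_df.itertuples():
        pid = row.patient_id
        sched = row.schedule
        pdir = root / pid
        if not pdir.is_dir():
            log.warning("%s: no image directory; excluded", pid)
            continue
        asg = assign_dose_bins(sched)
        images = {}
        first_mask = None
        for fx in range(1, sched.n_fractions + 1):
            ipath = pdir / f"fx{fx}_image.nii.gz"
            mpath = pdir / f"fx{fx}_mask.nii.gz"
            if not ipath.exists():
                continue
            vol = np.asarray(nib.load(ipath).dataobj, dtype=float)
            if mpath.exists():
                mask = np.asarray(nib.load(mpath).dataobj) > 0
            elif config.propagate_first_mask and first_mask is not None:
                mask = first_mask
            else:
                log.warning("%s fx%d: no mask; image skipped", pid, fx)
                continue
            if mask.shape != vol.shape:
                raise ValueError(f"{pid} fx{fx}: mask/volume grid mismatch")
            if fx == 1:
                first_mask = mask
            images[fx] = (vol, mask)
        patients[pid] = {"assignment": asg, "images": images}
        assignments[pid] = asg
    if not patients:
        raise ValueError("no usable patients in cohort")
    return patients, assignments, labels


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run on an on-disk cohort (``config.cohort_root``) and write artifacts."""
    if not config.cohort_root:
        raise ValueError("config.cohort_root is required")
    patients, assignments, labels = load_cohort_dir(Path(config.cohort_root), config)
    features = extract_cohort_features(patients, config)
    result = analyze_cohort(features, assignments, labels, config)
    if config.output_dir:
        write_artifacts(result, Path(config.output_dir))
    return result


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    """Feature CSV, per-bin delta/importance/AUC artifacts and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(outdir / "features.csv", index=False)
    for tag in BIN_TAGS:
        low = tag.lower()
        result.delta_tables[tag].to_csv(outdir / f"delta_{low}.csv")
        result.rankings[tag].to_frame().to_csv(outdir / f"importance_{low}.csv", index=False)
        np.savetxt(
            outdir / f"aucs_{low}.csv",
            result.reports[tag].aucs,
            fmt="%.10f",
            header="auc",
            comments="",
        )
        (outdir / f"validation_{low}.json").write_text(
            json.dumps(result.reports[tag].summary(), indent=2, sort_keys=True) + "\n"
        )
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
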