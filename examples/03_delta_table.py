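"""Delta features: change of the texture panel against baseline.

Generates a small synthetic longitudinal cohort in which responders'
texture drifts at the BED20 image, forms the per-patient delta tables for
both dose bins, and summarizes the group-mean percent change of one
feature - the increase-is-negative convention used for reporting.
"""

import numpy as np

from deltarad import CohortSpec, PipelineConfig, generate_cohort
from deltarad.delta import build_delta_table
from deltarad.pipeline import extract_cohort_features

cohort = generate_cohort(CohortSpec(n_patients=12, n_responders=6, seed=5))
patients = {
    p.patient_id: {
        "assignment": p.assignment,
        "images": {k + 1: (p.volumes[k], p.masks[k]) for k in range(p.n_fractions)},
    }
    for p in cohort.patients
}
features = extract_cohort_features(patients, PipelineConfig())

for tag in ("BED20", "BED40"):
    table = build_delta_table(
        features, cohort.assignments, cohort.labels, tag, convention="percent_change"
    )
    col = table.data["glcm.contrast"]
    rs = col[table.labels == "RS"].mean()
    nr = col[table.labels == "NR"].mean()
    print(f"{tag}: mean % change of GLCM contrast  RS {rs:+7.1f}%   NR {nr:+7.1f}%")

print("\nResponders' contrast falls at BED20 (positive percent change: the")
print("drift smooths the tumor field; a rise would print negative),")
print("non-responders hover near zero; by BED40 both groups are back near")
print("their pre-treatment texture.")
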