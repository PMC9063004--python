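"""The end-to-end analysis on a default synthetic cohort.

Thirty patients (11 responders / 19 non-responders) with the reference
fractionation mix; responders' texture drifts only at the BED20 image.
The pipeline extracts features, builds both delta tables, selects the top
two features per bin, and validates each pair. Expected behavior: strong
separation at BED20, none carried by the early signature at BED40.
"""

from deltarad import CohortSpec, PipelineConfig, generate_cohort, run_cohort
from deltarad.validation import bootstrap_validate

cohort = generate_cohort(CohortSpec(seed=1))
result = run_cohort(cohort, PipelineConfig(seed=1))

for tag in ("BED20", "BED40"):
    rep = result.reports[tag]
    print(f"{tag}: selected {result.selected[tag]}")
    print(f"       mean AUC = {rep.mean_auc:.3f} "
          f"[{rep.percentile_2_5:.3f}, {rep.percentile_97_5:.3f}]")

persist = bootstrap_validate(
    result.delta_tables["BED40"].dropna(), result.selected["BED20"],
    n_iter=1000, seed=1,
)
print(f"\nBED20-selected pair evaluated on the BED40 table: "
      f"mean AUC = {persist.mean_auc:.3f}")
print("\nThe early (BED20) delta signature is strongly predictive; it does")
print("not persist at BED40, where no class-dependent drift exists. The")
print("per-bin BED40 number sits above chance purely through selection")
print("optimism - 30 patients, best 2 of 39 features, scored in-sample.")
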