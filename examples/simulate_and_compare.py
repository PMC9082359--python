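"""Simulate a small synthetic cohort and run the full comparison.

Generates HR-deficient and HR/MMR-intact cases with the published
intra-tumoral intensity contrast (CD8 131.1 vs 40.5 cells/mm^2), runs
the whole pipeline (geometry -> compartments -> metrics -> classification
-> statistics) and prints the group comparison. With the reduced cohort
size used here the intra-tumoral CD8 contrast is usually, but not
always, significant; at the published sizes (25 vs 166) it almost
always is.
"""

import warnings

from pdactme import run_pipeline
from pdactme.simulate import CohortSimConfig, generate_cohort

cfg = CohortSimConfig(
    n_cases_per_group={"HR_d": 12, "HR_MMR_intact": 30},
    seed=20240901,
)
cohort = generate_cohort(cfg)
print(f"cohort: {len(cohort.clinical)} cases, {len(cohort.cells)} cells "
      f"on {len(cohort.cluster_sets)} cores")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_pipeline(cohort.cells, cohort.annotations, cohort.clinical)

print(f"classifier subgroup counts: {report['subgroup_counts']}")
print("\nCD8 density comparisons (cells/mm^2, mean over cases):")
for row in report["comparison"]["density_comparisons"]:
    if row["phenotype"] == "CD8":
        print(f"  {row['zone']:>14}: HR-d {row['mean_HR_d']:7.1f} "
              f"vs intact {row['mean_HR_MMR_intact']:7.1f}  "
              f"Wilcoxon p = {row['p_value']:.4g}")
ratio = report["comparison"]["ratio_comparison"]
print(f"\nCD8:FOXP3 ratio: HR-d {ratio['mean_HR_d']:.1f} vs "
      f"intact {ratio['mean_HR_MMR_intact']:.1f} (p = {ratio['p_value']:.3f})")
cpsr = report["comparison"]["cps_comparison"]
print(f"PD-L1 CPS >= 1 table {cpsr['positivity_table']}, "
      f"Fisher p = {cpsr['positivity_p_value']:.4g}")
surv = report["comparison"]["survival"]
print(f"KM median OS (months): {surv['medians']}  "
      f"log-rank p = {surv['logrank_p_value']:.3f}")
print(
    "\nOnly the intra-tumoral CD8 comparison is simulated with a group "
    "effect; peri-tumoral\nand stromal intensities are equal by "
    "construction, so their p-values behave as null."
)
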