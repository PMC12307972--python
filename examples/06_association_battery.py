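"""Run an individual-level association battery with BH-FDR correction.

Each cell regresses a wealth variable on a cycle metric (mixed model,
village random intercept, standardized coefficients); only q < 0.05
cells survive into the heatmap mask.
"""

from cyclewealth import VillageSpec, assemble_analysis_table, generate_cohort, run_battery
from cyclewealth.models import heatmap_table

cohort = generate_cohort(12, VillageSpec(gain_effect_quality=1.0), seed=2)
table = assemble_analysis_table(cohort, K=3)
print(f"analysis table: {len(table)} persons x {table.shape[1]} columns")

results = run_battery(table, families=("quality_cross", "quality_long"), K=(3,))
cols = ["family", "outcome", "coef", "se", "p", "q", "significant"]
print(results[cols].round(4).to_string(index=False))

print("\nheatmap mask (NaN = not significant after BH):")
print(heatmap_table(results).round(3).to_string())
print("\nThe longitudinal quality row for the wealth index is positive and "
      "significant because this cohort was generated with a planted effect of "
      "cycle quality on wealth gain (log-odds 1.0 per SD).")
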