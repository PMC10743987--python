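"""Simulate a small female/male cohort and test the sex contrasts.

Group means encode the reported contrasts (female APD90 37% longer, male
contraction velocity 29% higher, Ca2+ release/reuptake ~15% faster in
males); per-cell parameters are drawn log-normally (CV 0.15) and every
cell is pushed through the full imaging + analysis pipeline before a
per-cell Mann-Whitney comparison.
"""

import pandas as pd

from ecckymo import (AnalysisConfig, SimCellParams, analyze_run,
                     compare_conditions, generate_cohort, summarize)

base = SimCellParams(n_lines=2000)   # one beat per cell keeps this quick
rows = []
for cell in generate_cohort(n_cells_per_group=15, seed=0, base_params=base):
    cfg = AnalysisConfig(beats_to_analyze=1,
                         search_start_ms=max(cell.params.first_stim_ms - 50, 0))
    result = analyze_run(cell.kymograph, cfg)
    if result.status == "ok":
        rows.extend(result.to_rows())
table = pd.DataFrame(rows)

print(summarize(table[["condition", "animal_id", "run_id", "beat",
                       "v_tau90_ms", "contraction_velocity_um_per_ms"]],
                level="cell").to_string(index=False))

for metric in ("v_tau90_ms", "contraction_velocity_um_per_ms"):
    r = compare_conditions(table, metric)
    print(f"\n{metric}: median {r.conditions[0]} = {r.medians[0]:.4g}, "
          f"{r.conditions[1]} = {r.medians[1]:.4g}, "
          f"Mann-Whitney p = {r.p_value:.2e}")

print("\nAPD90 (the voltage Tau90) comes out longer in females and the "
      "contraction velocity higher in males, matching the programmed "
      "contrasts; p-values are from the per-cell two-sided test.")
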