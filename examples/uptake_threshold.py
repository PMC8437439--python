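"""Cytosolic Ca2+ threshold for mitochondrial uptake in imaged cells.

Simulates thapsigargin-evoked cytosolic Ca2+ rises with a delayed
mitochondrial (Cepia) response: WT-like cells start mitochondrial uptake
near 400 nM cytosolic Ca2+, MICU1-KO-like cells at the resting level.
The detector smooths the mitochondrial F/F0 with a zero-phase Butterworth
filter and takes the earliest frame whose derivative exceeds 80 % of the
maximal derivative; the fura-2 ratio at that frame gives the threshold.
"""

import numpy as np

from mcugate import analyze_trace, batch_thresholds, default_imaging_model, simulate_imaging

rows = []
for g, (genotype, programmed) in enumerate((("WT", 400.0), ("MICU1-KO", 100.0))):
    for dish in range(3):
        for cell in range(5):
            model = default_imaging_model(threshold_ca_nM=programmed)
            trace = simulate_imaging(
                model, seed=10_000 * g + 100 * dish + cell,
                cell_id=f"c{cell}", dish_id=f"{genotype}-d{dish}", genotype=genotype,
            )
            res = analyze_trace(trace)
            rows.append((genotype, f"{genotype}-d{dish}", res.threshold_ca_nM))

batch = batch_thresholds(rows)
for genotype in ("WT", "MICU1-KO"):
    print(f"{genotype:10s} threshold = {batch.group_means[genotype]:6.0f} "
          f"+/- {batch.group_sems[genotype]:.0f} nM (SEM over 3 dishes)")
print(f"one-way ANOVA on dish means: F = {batch.anova_F:.1f}, p = {batch.anova_p:.2g}")
print(
    "\nWT cells delay mitochondrial uptake until ~400 nM cytosolic Ca2+;"
    "\nwithout MICU1 the threshold collapses to the resting level."
)
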