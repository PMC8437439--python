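"""Compare single-channel open probability between WT and MICU1-KO.

The gating model multiplies closed->open transition probabilities by a
Hill function of cytosolic Ca2+ (EC50 at the EF-hand Kd, ~600 nM) in WT
but not in the knockout, so at saturating Ca2+ the programmed Po contrast
is 0.5 vs 0.2. Small simulated ensembles recover the ratio with equal
unitary amplitudes — the knockout changes gating, not the pore.
"""

from mcugate import (
    compare_genotypes,
    default_gating_model,
    idealize_recording,
    simulate_single_channel,
)

base = default_gating_model()
groups = {}
for g, genotype in enumerate(("WT", "MICU1-KO")):
    model = base.potentiated(105e6, genotype)
    stats = []
    for i in range(3):
        rec, _ = simulate_single_channel(
            model, duration=30.0, seed=1000 * g + i, genotype=genotype
        )
        stats.append(idealize_recording(rec, K=4, seed=0)[2])
    groups[genotype] = stats

po = compare_genotypes(groups, metric="p_open")
amp = compare_genotypes(groups, metric="full_amplitude")

for label, mean, sem in zip(po.labels, po.means, po.sems):
    print(f"{label:10s} Po = {mean:.3f} +/- {sem:.3f} (SEM, n=3)")
print(f"Po ratio WT/KO = {po.ratio_of_means:.2f}  (programmed 2.5)")
print(f"two-tailed unpaired t-test p = {po.p_value:.2g}")
print(f"full-amplitude ratio = {amp.ratio_of_means:.3f}  (programmed 1.0)")
print(
    "\nA Po ratio near 2.5 with an amplitude ratio near 1 reproduces the"
    "\nsignature of MICU potentiation acting on gating, not conductance."
)
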