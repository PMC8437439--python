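"""Whole-mitoplast ramp metrics, Mg2+ block fit, and exchange kinetics.

Simulates -160 -> +80 mV ramp sweeps, reads current densities at the
standard voltages, fits the Hill curve of Mg2+ inhibition of the Ca2+
current, the one-site Ca2+ block of the Na+ current, and a
single-exponential activation transient at the solution-exchange
timescale.
"""

import numpy as np

from mcugate import (
    current_at_voltage,
    default_ramp_model,
    fit_ca_block_of_ina,
    fit_exponential_kinetics,
    fit_hill_inhibition,
    rectification_index,
    simulate_ramp,
)

model = default_ramp_model()

wt = simulate_ramp(model, ca_i_uM=1000.0, genotype="WT", seed=1)
ko = simulate_ramp(model, ca_i_uM=1000.0, genotype="MICU1-KO", seed=2)
for name, sweep in (("WT", wt), ("MICU1-KO", ko)):
    i, d = current_at_voltage(sweep, -160.0)
    print(f"{name:10s} I_Ca(-160 mV) = {i:8.1f} pA  ({d:.0f} pA/pF)")

# Mg2+ dose-inhibition measured from simulated sweeps, normalized to Mg-free
mg_concs = [0.0, 30.0, 100.0, 300.0, 1000.0, 3000.0]
i0 = current_at_voltage(simulate_ramp(model, ca_i_uM=1000, mg_i_uM=0, seed=3), -160)[0]
points = []
for j, mg in enumerate(mg_concs):
    sweep = simulate_ramp(model, ca_i_uM=1000.0, mg_i_uM=mg, seed=10 + j)
    points.append((mg, current_at_voltage(sweep, -160.0)[0] / i0))
hill = fit_hill_inhibition(points)
print(f"\nMg2+ block: IC50 = {hill.ic50:.0f} +/- {hill.ic50_se:.0f} uM, "
      f"n_H = {hill.n_h:.2f} (simulated with IC50 149 uM, n_H 0.9)")

# Ca2+ block of the Na+ current (Kd ~2 nM scenario)
ca_nM = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 20.0])
resp = 1.0 / (1.0 + ca_nM / 2.0)
kd_fit = fit_ca_block_of_ina(list(zip(ca_nM, resp)))
print(f"Ca2+ block of I_Na: Kd = {kd_fit.ic50:.2f} nM (scenario 2 nM)")

# activation kinetics after a fast solution switch (tau ~0.4 ms)
t = np.arange(0.0, 0.008, 1e-5)
trace = -150.0 * (1.0 - np.exp(-t / 4e-4))
kin = fit_exponential_kinetics(t, trace, "activation")
print(f"activation tau = {kin.tau * 1e3:.3f} ms (scenario 0.4 ms)")

rect = rectification_index(simulate_ramp(model, ca_i_uM=1000.0, matrix_ca_mM=2.0, seed=4))
print(f"rectification index |I(+80)|/|I(-160)| = {rect:.4f}")
print(
    "\nThe WT/KO density ratio near 2 reflects MICU potentiation; the"
    "\nnear-zero rectification index shows the outward limb is suppressed"
    "\neven with 2 mM matrix Ca2+."
)
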