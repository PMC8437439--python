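# mcugate

Quantitative analysis of how the MICU subunits gate the mitochondrial
calcium uniporter (MCU) — the Ca²⁺-selective channel complex of the inner
mitochondrial membrane. The package implements, as a tested reusable
library, the four measurement pipelines by which this regulation is
quantified, together with synthetic-data generators that carry known
ground truth so every stage is validated by parameter recovery:

1. **Single-channel idealization** — a noisy patch-clamp current trace is
   decimated by block averaging (50 kHz → 2.5 kHz) and decoded into a
   sequence of conductance levels (closed + open sublevels at ~100/80/60 %
   of the full amplitude) with a Gaussian-emission hidden Markov model:
   Baum–Welch (EM) fitting, Viterbi decoding, and derived statistics.
   The time-averaged unitary current is

   $$\bar i = \sum_k p_k\, i_k$$

   the occupancy-weighted sum of level amplitudes; the open probability
   is $P_o = 1 - p_{\mathrm{closed}}$. The MICU subunits act as Ca²⁺
   sensors that multiply closed→open transition probabilities as a Hill
   function of cytosolic [Ca²⁺] (EC50 near the EF-hand K_d ≈ 600 nM)
   without changing the unitary amplitudes.

2. **Whole-mitoplast ramp currents** — I–V sweeps (−160 → +80 mV, voltages
   on the matrix side, inward current negative) yield current densities
   (pA/pF), paired current ratios (I_Ca/I_Na, I_Mn/I_Ca), Hill fits of
   Mg²⁺ inhibition $f([\mathrm{Mg}]) = 1/(1+([\mathrm{Mg}]/IC_{50})^{n_H})$,
   one-site Ca²⁺ block of the Na⁺ current, single-exponential
   activation/deactivation kinetics after fast solution exchange
   (τ ~ 0.4 ms), and the inward-rectification index |I(+80)|/|I(−160)|.

3. **Flux → chord conductance** — in isolated-mitochondria uptake assays,
   indicator fluorescence is calibrated (ratiometric Grynkiewicz equation
   for fura-2; one-site form for Fluo-4/Fluo4-FF), the buffer equilibrium
   is inverted to total extramitochondrial Ca²⁺, the uptake flux *J* is
   the slope over the first 20 s, and the whole-membrane conductance
   follows from the chord relation

   $$I = G\,(\Delta\Psi_m - E_{\mathrm{Ca}}), \qquad I = -zFJ,\qquad
     E_{\mathrm{Ca} } = \frac{RT}{2F}\ln\frac{[\mathrm{Ca}]_i}{[\mathrm{Ca}]_m}$$

4. **Uptake-threshold detection** — in paired cytosolic (fura-2) /
   mitochondrial (Cepia) imaging traces, the mitochondrial F/F0 signal is
   smoothed with a zero-phase 2nd-order Butterworth filter and the
   upstroke is the earliest frame between baseline and peak whose time
   derivative exceeds 80 % of the maximal derivative; the cytosolic
   [Ca²⁺] at that frame is the uptake threshold (~400 nM in WT-like
   conditions, collapsing to the resting level without MICU1).

The intended users are channel biophysicists and mitochondrial
physiologists who need these analyses scripted, seeded, and testable
rather than run through GUI tools.

## Worked example

```bash
python examples/single_channel_idealization.py
```

prints (seeded, reproducible):

```
fitted level amplitudes (pA): [-0.012 -2.    -1.597 -1.159]
occupancy probabilities:      [0.512 0.221 0.155 0.112]
open probability Po = 0.488  (simulated at 0.5)
time-averaged unitary current i_avg = -0.825 pA
per-sample decoding accuracy vs ground truth: 98.6%
```

The four fitted levels recover the programmed closed level and the
100/80/60 % open sublevels of the −2 pA full amplitude; the occupancy
vector and Po match the gating model the trace was simulated from, and
the time-averaged current equals the occupancy-weighted amplitude sum.
Other examples cover the WT vs MICU1-KO open-probability contrast
(`genotype_po_comparison.py`), ramp metrics and block/kinetics fits
(`ramp_metrics_and_fits.py`), the flux-to-conductance closed loop
(`flux_conductance.py`), and dish-level threshold statistics
(`uptake_threshold.py`).

A thin CLI mirrors the library for shell use:

```bash
mcugate simulate --kind imaging --seed 1 --out cell.csv
mcugate threshold cell.csv
```

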