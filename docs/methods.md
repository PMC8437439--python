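# Methods

This note records the models behind each pipeline stage, the default
parameters and why they were chosen, the numerical decisions, and what
the synthetic data do and do not emulate.

## Conventions

Voltages are on the matrix side of the inner membrane relative to the
cytosolic side; currents into the matrix are negative. z = 2 and
F = 96485 C/mol are fixed; the default temperature is 298.15 K
(room-temperature assays). All generators are pure functions of
(model, seed); every stochastic analysis step takes an explicit seed.

## Single-channel gating model and idealization

**Generative model.** A first-order Markov chain over K = 4 conductance
levels: closed (0 pA) and open sublevels at 100/80/60 % of the full
amplitude (−2.0 pA for Ca²⁺ at −120 mV, −2.6 pA for Na⁺). Transition
probabilities are defined per sampling step at a declared base rate
(50 kHz) and rescaled by matrix power when simulating or analysing at
another rate, so the ground truth is well defined across rates. Defaults:
total closed→open probability 5·10⁻⁴ per step split 0.5/0.3/0.2 over the
sublevels (mean closed dwell ~40 ms) and open→closed probability 2·10⁻³
(mean open dwell ~10 ms). These dwells were chosen so that events are
individually resolved at the 2.5 kHz analysis rate, as in the recordings
the generator emulates; the recording durations (default 60 s per
voltage) are a package choice, since no per-voltage durations are
standard. The baseline open probability is 0.2.

**MICU potentiation.** The Ca²⁺-sensing subunits multiply the
closed→open probabilities by a Hill factor
fold(Ca) = 1 + (max_fold − 1)·Ca/(Ca + EC50), EC50 = 600 nM (the EF-hand
K_d), max_fold = 4. At saturating Ca²⁺ this raises Po from 0.2 to 0.5 —
a 2.5-fold contrast between the potentiated (WT) and unpotentiated (KO)
channel — while amplitudes are untouched: potentiation acts on gating,
not permeation. Knockout genotypes (any label containing "KO") never
potentiate; Na⁺-mode recordings are Ca²⁺-free, so both genotypes share
one gating model there.

**Noise and filtering.** White Gaussian noise (0.6 pA SD at 50 kHz) is
added before a forward-backward 2nd-order Butterworth filter at 1 kHz —
a zero-phase digital stand-in for the hardware anti-alias filter, with
the cutoff recorded in the metadata. After block-average decimation to
2.5 kHz the effective noise is ~0.13 pA, so adjacent sublevels (0.4 pA
apart) are ~3 SD apart.

**Idealization.** Decimation is by non-overlapping block averaging with
the trailing partial block dropped; non-integer decimation factors are
rejected. The HMM has Gaussian emissions with a shared SD by default
(per-level optional); Baum–Welch uses scaled forward–backward recursions
(compiled with numba), stops when the log-likelihood gain drops below
10⁻⁶ per sample or at 500 iterations, and is restarted from 1-D k-means
centers, evenly spaced quantiles, and five seeded random quantile draws,
keeping the best final likelihood. The initial shared SD comes from a
robust first-difference estimator (median |Δx| / (√2·0.6745)): a
too-large starting SD merges neighbouring sublevels in the first E-step
and strands EM in a merged-level optimum. The closed level is identified
as the fitted mean nearest 0 pA; levels are reported closed-first, then
by decreasing amplitude magnitude. Viterbi decoding runs in the log
domain. Occupancies are decoded-state frequencies; Po = 1 − p(closed);
the time-averaged unitary current is Σ p_k·i_k, which equals the mean of
the noise-free reconstructed trace by construction.

**Dead-time correction and known approximations.** The acquisition
filter correlates neighbouring samples and smears level transitions
across block boundaries; the HMM ignores both (as the standard workflow
does). The visible consequence is that filter-edge samples between the
closed and full levels masquerade as single-sample visits to the
intermediate sublevel. Since the 1 kHz filter cannot convey events
shorter than its rise time and decimation smears edges across one
2.5 kHz sample, decoded sojourns shorter than 2 resampled samples
(0.8 ms) are treated as artifacts and merged into the preceding level
before statistics are computed (`suppress_brief_events`; disable with
``min_dwell_samples=1``). With this correction, amplitudes, occupancies
and Po are recovered to a few percent or better on filtered synthetic
data. EM transition-probability estimates remain edge-biased for
weakly-occupied sublevels, so transition-matrix recovery to 0.02
absolute is verified on unfiltered synthesis (conditionally independent
emissions), where it isolates the estimator itself; the filtered
pipeline is held to the amplitude/occupancy/Po criteria.

## Whole-mitoplast ramp model and metrics

The phenomenological sweep model is I(V) = A·r(V) + g_leak·V + noise,
with the open-channel shape r(V) = V·σ(−V/10 mV) — linear on the inward
limb, suppressed outward limb (|r(+80)|/|r(−160)| < 0.1 %), matching
inward rectification regardless of matrix Ca²⁺. The amplitude A is
g_max·sat(Ca)·block(Mg)·genotype for Ca²⁺ (sat half-saturating at
50 µM; genotype multiplies by micu_factor = 2 for WT), g_max·(1/7)·sat·
genotype for Mn²⁺, and g_Na·(1+[Ca]/2 nM)⁻¹·block(Mg) for Na⁺ — the
Na⁺ mode requires a divalent-free bath and is genotype-independent.
Mg²⁺ block is Hill inhibition (IC50 149 µM, n_H 0.9) with an optional
competitive mode IC50·(1 + [Ca]/ca_half). Defaults g_max = 0.35 nS,
g_Na = 0.7 nS, capacitance 0.4 pF, noise 1.5 pA give WT densities of
order 10² pA/pF at −160 mV.

Measurements exclude 2 ms at the protocol edges (capacitance-transient
region). A stated-voltage reading fits a local line to the samples
within ±2 mV and evaluates it at the target voltage — this averages
noise, is exact for a locally linear I–V, and stays unbiased when the
window is clipped at a ramp edge. Default measurement voltages: −160 mV
for I_Ca/I_Mn, −80 mV for I_Na, +80 mV for the outward check. The
rectification index instead uses plain ±5 mV window means, since a
fitted line extrapolated at the edge would amplify noise around a
near-zero outward current. Hill and exponential fits use seeded
multi-start least squares (5 starts) with f(0) = 1 fixed by the
functional form, matching normalization to the block-free current; a
dose–response is flagged (not rejected) when any upward step between
consecutive concentrations exceeds 10 % of that normalized scale.

## Flux → chord conductance

**Assay model.** Mitochondria (0.5 mg/ml in a 200 µl well) are held at a
clamped ΔΨm (−160 mV) with constant matrix free Ca²⁺ (200 nM; matrix
buffering dominates over 35 s). Forward-Euler integration moves total
Ca²⁺ out of the bath compartment at the chord-conductance rate, with the
free concentration re-solved from the buffer equilibrium at every step,
so free + bound + cumulative uptake equals the amount added to solver
precision at every sample. Protocol 1 (≤3 µM added): Fluo-4 (3 µM,
K_d 0.345 µM) is the sole significant buffer and the indicator.
Protocol 2 (>3 µM): EGTA carried over from the resuspension and diluted
~20-fold into the well (2 µM at an apparent K_d of 0.15 µM for pH 7.2)
plus 1 µM Fluo4-FF (K_d 9.7 µM) as the low-affinity reporter — at these
ratios the µM-range free Ca²⁺ sits inside the indicator's sensitive
range. The default conductance (2·10⁴ nS/mg) produces declines of
~0.2 µM over the 20 s fit window, comparable to plate-reader assays;
photometric noise defaults to 2 a.u. on a 5000 a.u. indicator scale.

**Inference.** Indicator → free Ca²⁺ (one-site inversion), free → total
(forward sum over buffers), OLS slope over the first 20 s → J
(mol s⁻¹ mg⁻¹; normalizing per mg before or after the linear fit
commutes), I = −zFJ (inward negative), E_Ca from window-mean free Ca²⁺
vs matrix fura-2, G = I/(ΔΨm − E_Ca) with driving forces below 1 mV
rejected as undefined. ΔΨm is accepted directly, from record metadata,
or through a user-supplied monotone TMRM-ratio calibration — no dye
model is hard-coded. The equilibrium solver is bracketed root finding on
[0, total] (Brent, 10⁻¹⁵ relative), cross-checked against plain
bisection in the tests. The ratiometric fura-2 equation is implemented
in the standard Grynkiewicz form [Ca] = K_d·(R−Rmin)/(Rmax−R)·β with
β = F380max/F380min; readings at or above Rmax raise a saturation error
and sub-Rmin readings clamp to zero with a warning.

## Imaging threshold detection

The mitochondrial F/F0 (baseline = pre-stimulus mean) is smoothed with a
zero-phase 2nd-order Butterworth filter. The "optimal" cutoff is chosen
by residual analysis: the residual RMS between raw and filtered traces
is computed over a cutoff grid, the noise-dominated high-cutoff tail is
extrapolated linearly to zero cutoff, and the chosen cutoff is where the
residual curve first drops to that intercept; the fallback for 3-s frame
data is 0.03 Hz, and the value used is recorded in the result. Filtering
pads with even extension over ~4 filter time constants so the
forward–backward result is time-reversal symmetric to 10⁻⁹. The upstroke
is the earliest frame strictly between the baseline end and the global
peak whose central-difference derivative exceeds 0.8× the maximal
derivative in that interval (earliest index on ties; edge frames
excluded). The manual-check step of interactive workflows is replaced by
QC flags: peak-before-stimulus, criterion-at-boundary, saturated fura
ratio. Cell thresholds are aggregated to dish means before one-way
ANOVA with Tukey post-hoc, mirroring per-dish statistics. The default
cytosolic scenario is a linear post-stimulus ramp (5 nM/s from 100 nM
resting, plateau 1 µM) with the mitochondrial rise
1 + gain·(1 − e^(−t/τ)) after onset; on a 3-s frame grid the detector is
accurate to one frame, which bounds the threshold error at the ramp
slope × 3 s (~4 % at 400 nM).

## What the synthetic data do not emulate

Gating is strictly Markovian (no correlated or modal gating, no
dwell-time structure beyond exponential); ramp noise is white (no 1/f or
seal noise, no capacitance transients — the 2 ms edge exclusion is
therefore exercised only as a guard); the flux model has no Ca²⁺ efflux,
matrix-volume changes, or ΔΨm rundown; imaging has no bleaching, motion,
or segmentation error. Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated models, not robustness to
every artifact of real recordings.

## Problem sizes

The test suite and acceptance script use 60-s single-channel traces
(4–5 per genotype for contrasts, 20 for recovery), 12–20 flux assays
across 0.5–25 µM, 100–200 imaged cells, and exhaustive Viterbi checks
capped at K^T ≈ 2·10⁴ paths per instance — sizes at which every
statistical tolerance in the tests has comfortable margin on one CPU.
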