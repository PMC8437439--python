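"""Synthetic generators for the four recording modalities.

Every generator is a pure function of a model object and a seed, and
returns the recording together with (where applicable) the exact hidden
ground truth, so downstream analyses can be validated by parameter
recovery.

The generative picture is the gating model of the uniporter holocomplex:
the pore is constitutively active with a closed level and three open
(sub)conductance levels at 100/80/60 % of the full amplitude; the
EF-hand Ca2+ sensors (MICUs) multiply the closed-to-open transition
probabilities — and hence the open probability — as a Hill function of
cytosolic [Ca2+] with half-activation near the EF-hand Kd (~600 nM),
while leaving the unitary amplitudes untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import signal
from scipy.special import expit

from ._kernels import sample_markov_chain
from .records import FluxAssayRecord, ImagingTrace, RampSweep, SingleChannelRecording

__all__ = [
    "MicuPotentiation",
    "GatingModel",
    "RampProtocol",
    "RampModel",
    "Buffer",
    "Indicator",
    "FuraCalibration",
    "FluxModel",
    "ImagingModel",
    "default_gating_model",
    "default_ramp_model",
    "default_flux_model",
    "default_imaging_model",
    "stationary_distribution",
    "simulate_single_channel",
    "simulate_ramp",
    "simulate_flux_assay",
    "simulate_imaging",
]

FARADAY = 96485.33212  # C/mol
GAS_R = 8.31446261815324  # J/(mol K)


def _check_stochastic(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(mat < 0):
        raise ValueError("transition matrix has negative entries")
    if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must sum to 1 (within 1e-12)")
    return mat


def stationary_distribution(trans: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    trans = _check_stochastic(trans)
    w, v = np.linalg.eig(trans.T)
    idx = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


# --------------------------------------------------------------------------
# Single-channel gating
# --------------------------------------------------------------------------


@dataclass
class MicuPotentiation:
    """Hill-type multiplication of closed->open transition probabilities.

    fold(ca) = 1 + (max_fold - 1) * ca^h / (ca^h + ec50^h), ca in nM.
    ``max_fold`` is the saturating multiplier carried by a full MICU
    complement; knockouts use fold = 1 at any [Ca2+].
    """

    ec50_nM: float = 600.0
    hill: float = 1.0
    max_fold: float = 4.0

    def __post_init__(self) -> None:
        if self.ec50_nM <= 0:
            raise ValueError("EC50 must be positive")

    def fold(self, ca_nM: float) -> float:
        x = (ca_nM / self.ec50_nM) ** self.hill
        return 1.0 + (self.max_fold - 1.0) * x / (1.0 + x)


@dataclass
class GatingModel:
    """Markov gating model for a single uniporter channel.

    ``level_currents[0]`` is the closed level (exactly 0 pA); open levels
    follow in decreasing magnitude (full, ~80 %, ~60 %). The transition
    matrix is defined per sampling step at ``base_rate``; analyses at a
    different rate see its matrix power.
    """

    level_currents: np.ndarray
    transition_matrix: np.ndarray
    noise_sd: float = 0.6
    voltage: float = -120.0
    base_rate: float = 50_000.0
    micu_potentiation: MicuPotentiation = field(default_factory=MicuPotentiation)

    def __post_init__(self) -> None:
        self.level_currents = np.asarray(self.level_currents, dtype=float)
        self.transition_matrix = _check_stochastic(self.transition_matrix)
        if self.level_currents[0] != 0.0:
            raise ValueError("level 0 (closed) current must be exactly 0 pA")
        opens = self.level_currents[1:]
        if opens.size and not (np.all(opens > 0) or np.all(opens < 0)):
            raise ValueError("open-level currents must share one sign")
        if self.level_currents.size != self.transition_matrix.shape[0]:
            raise ValueError("level count must match transition matrix size")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_levels(self) -> int:
        return self.level_currents.size

    def potentiated(self, ca_nM: float, genotype: str = "WT") -> "GatingModel":
        """Model with MICU potentiation applied at cytosolic ``ca_nM``.

        Multiplies the closed-row open-ward probabilities by the Hill fold
        (knockout genotypes containing ``"KO"`` are left unpotentiated) and
        restores row normalization through the closed self-transition.
        """
        fold = 1.0 if "KO" in genotype.upper() else self.micu_potentiation.fold(ca_nM)
        trans = self.transition_matrix.copy()
        trans[0, 1:] = trans[0, 1:] * fold
        leave = trans[0, 1:].sum()
        if leave >= 1.0:
            raise ValueError("potentiation drives closed-row probability above 1")
        trans[0, 0] = 1.0 - leave
        return replace(self, transition_matrix=trans)

    def open_probability(self) -> float:
        """Stationary open probability implied by the transition matrix."""
        pi = stationary_distribution(self.transition_matrix)
        return float(1.0 - pi[0])


def default_gating_model(
    permeant: str = "Ca",
    voltage: float = -120.0,
    noise_sd: float = 0.6,
) -> GatingModel:
    """Baseline 4-level gating model (closed + 100/80/60 % sublevels).

    The closed-to-open rate constants give a ~40 ms mean closed dwell and
    ~10 ms mean open dwell at the 50 kHz base rate — events long enough
    that sublevels are individually resolved at the 2.5 kHz analysis
    rate, as in the recordings this emulates — for a baseline (MICU-free)
    open probability of 0.2; full potentiation (fold 4) raises it to 0.5.
    For Na+ as permeant the full level is larger and potentiation is
    absent by construction of the Ca2+-free condition.
    """
    full = -2.0 if permeant == "Ca" else -2.6
    levels = np.array([0.0, full, 0.8 * full, 0.6 * full])
    p_open_total = 5e-4
    weights = np.array([0.5, 0.3, 0.2])
    p_close = 2e-3
    trans = np.zeros((4, 4))
    trans[0, 1:] = p_open_total * weights
    trans[0, 0] = 1.0 - p_open_total
    for k in range(1, 4):
        trans[k, 0] = p_close
        trans[k, k] = 1.0 - p_close
    return GatingModel(
        level_currents=levels,
        transition_matrix=trans,
        noise_sd=noise_sd,
        voltage=voltage,
    )


def simulate_single_channel(
    model: GatingModel,
    duration: float = 60.0,
    sample_rate: float = 50_000.0,
    filter_cutoff: float | None = 1_000.0,
    seed: int = 0,
    permeant_ion: str = "Ca",
    genotype: str = "WT",
) -> tuple[SingleChannelRecording, np.ndarray]:
    """Simulate a filtered single-channel trace plus its hidden state path.

    The Markov path is sampled at ``sample_rate`` (transition matrix
    rescaled by matrix power if the rate differs from the model's base
    rate), white Gaussian noise is added, and the sum is passed through a
    forward-backward 2nd-order Butterworth filter at ``filter_cutoff``
    (``None`` skips the acquisition filter: samples are then
    conditionally independent given the state path).

    Returns ``(recording, states)`` where ``states`` is the exact hidden
    level index per sample.
    """
    n = int(round(duration * sample_rate))
    if n < 10:
        raise ValueError("duration * sample_rate must be at least 10 samples")
    if filter_cutoff is not None and filter_cutoff >= sample_rate / 2:
        raise ValueError("filter_cutoff must be below the Nyquist frequency")

    trans = model.transition_matrix
    if sample_rate != model.base_rate:
        step = model.base_rate / sample_rate
        if abs(step - round(step)) > 1e-9 or step < 1:
            raise ValueError(
                "sample_rate must divide base_rate for transition rescaling"
            )
        trans = np.linalg.matrix_power(trans, int(round(step)))

    rng = np.random.default_rng(seed)
    pi = stationary_distribution(trans)
    start = int(rng.choice(model.n_levels, p=pi))
    uniforms = rng.random(n - 1)
    states = sample_markov_chain(np.cumsum(trans, axis=1), start, uniforms)
    clean = model.level_currents[states]
    noisy = clean + rng.normal(0.0, model.noise_sd, size=n)
    if filter_cutoff is not None:
        sos = signal.butter(2, filter_cutoff, fs=sample_rate, output="sos")
        noisy = signal.sosfiltfilt(sos, noisy)
    rec = SingleChannelRecording(
        samples=noisy,
        sample_rate=sample_rate,
        filter_cutoff=filter_cutoff if filter_cutoff is not None else np.inf,
        voltage=model.voltage,
        permeant_ion=permeant_ion,
        genotype=genotype,
    )
    return rec, states


# --------------------------------------------------------------------------
# Whole-mitoplast ramp currents
# --------------------------------------------------------------------------


@dataclass
class RampProtocol:
    """Voltage-ramp protocol: linear sweep v_start -> v_end."""

    v_start: float = -160.0
    v_end: float = 80.0
    duration_s: float = 0.75
    sample_rate: float = 10_000.0

    def voltages(self) -> tuple[np.ndarray, np.ndarray]:
        n = int(round(self.duration_s * self.sample_rate)) + 1
        t = np.linspace(0.0, self.duration_s, n)
        v = np.linspace(self.v_start, self.v_end, n)
        return t, v


def _inward_rectifier(v_mV: np.ndarray, slope_mV: float = 10.0) -> np.ndarray:
    """Open-channel I-V shape: ~linear inward limb, outward limb suppressed.

    Returns a signed shape in mV units so that (conductance nS) * shape
    gives pA; at +80 mV the magnitude is <0.1 % of the -160 mV limb.
    """
    return v_mV * expit(-np.asarray(v_mV, dtype=float) / slope_mV)


@dataclass
class MgBlock:
    ic50_uM: float = 149.0
    n_h: float = 0.9
    competitive: bool = False


@dataclass
class RampModel:
    """Phenomenological whole-mitoplast current model.

    Inward current = g_max * saturation([Ca2+]i) * Mg-block * genotype
    factor * rectifier shape(V). The MICU complement multiplies the
    amplitude ~2-fold (``micu_factor``) for Ca2+ (and Mn2+) but not Na+;
    Na+ current is blocked by nM cytosolic Ca2+ (``na_block_kd_nM``) and
    by Mg2+.
    """

    g_max: float = 0.35  # nS, MICU-free Ca2+ conductance scale
    ca_half: float = 50.0  # µM, half-saturating bath [Ca2+]
    micu_factor: float = 2.0
    mg_block: MgBlock = field(default_factory=MgBlock)
    na_block_kd_nM: float = 2.0
    na_gmax: float = 0.7  # nS
    mn_factor: float = 1.0 / 7.0  # I_Mn relative to I_Ca at saturation
    capacitance: float = 0.4  # pF
    noise_sd_pA: float = 1.5
    leak_nS: float = 0.0
    rectification: Callable[[np.ndarray], np.ndarray] = _inward_rectifier

    def __post_init__(self) -> None:
        for name in ("g_max", "ca_half", "micu_factor", "na_block_kd_nM",
                     "na_gmax", "mn_factor", "capacitance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def default_ramp_model(**kwargs) -> RampModel:
    return RampModel(**kwargs)


def _hill_inhibition(x: float, ic50: float, n_h: float) -> float:
    if x <= 0:
        return 1.0
    return 1.0 / (1.0 + (x / ic50) ** n_h)


def simulate_ramp(
    model: RampModel,
    protocol: RampProtocol | None = None,
    ca_i_uM: float = 1000.0,
    mg_i_uM: float = 0.0,
    mn_i_uM: float = 0.0,
    permeant: str = "Ca",
    genotype: str = "WT",
    matrix_ca_mM: float = 0.0,
    seed: int = 0,
) -> RampSweep:
    """Simulate one voltage-ramp sweep under the stated bath condition.

    The genotype factor multiplies Ca2+- and Mn2+-carried currents only;
    Na+ current is genotype-independent and requires (near) divalent-free
    bath. Additive Gaussian noise models baseline recording noise.
    """
    if min(ca_i_uM, mg_i_uM, mn_i_uM) < 0 or matrix_ca_mM < 0:
        raise ValueError("concentrations must be non-negative")
    protocol = protocol or RampProtocol()
    t, v = protocol.voltages()
    shape = model.rectification(v)
    geno = model.micu_factor if "KO" not in genotype.upper() else 1.0

    if permeant == "Ca":
        sat = ca_i_uM / (ca_i_uM + model.ca_half)
        ic50 = model.mg_block.ic50_uM
        if model.mg_block.competitive:
            ic50 = ic50 * (1.0 + ca_i_uM / model.ca_half)
        block = _hill_inhibition(mg_i_uM, ic50, model.mg_block.n_h)
        mn_pore_block = _hill_inhibition(mn_i_uM, 1000.0, 1.0)
        amp = model.g_max * sat * block * mn_pore_block * geno
    elif permeant == "Mn":
        sat = mn_i_uM / (mn_i_uM + model.ca_half)
        amp = model.g_max * model.mn_factor * sat * geno
    elif permeant == "Na":
        ca_nM = ca_i_uM * 1e3
        ca_block = 1.0 / (1.0 + ca_nM / model.na_block_kd_nM)
        mg_blk = _hill_inhibition(mg_i_uM, model.mg_block.ic50_uM, 1.0)
        amp = model.na_gmax * ca_block * mg_blk
    else:
        raise ValueError(f"unknown permeant ion {permeant!r}")

    current = amp * shape + model.leak_nS * v
    rng = np.random.default_rng(seed)
    current = current + rng.normal(0.0, model.noise_sd_pA, size=current.size)
    return RampSweep(
        time=t,
        voltage=v,
        current=current,
        capacitance=model.capacitance,
        condition={
            "permeant": permeant,
            "ca_i_uM": ca_i_uM,
            "mg_i_uM": mg_i_uM,
            "mn_i_uM": mn_i_uM,
            "matrix_ca_mM": matrix_ca_mM,
            "genotype": genotype,
        },
    )


# --------------------------------------------------------------------------
# Isolated-mitochondria flux assays
# --------------------------------------------------------------------------


@dataclass
class Buffer:
    name: str
    total_uM: float
    kd_uM: float

    def __post_init__(self) -> None:
        if self.total_uM < 0 or self.kd_uM <= 0:
            raise ValueError("buffer totals must be >= 0 and Kd > 0")


@dataclass
class Indicator:
    """Single-wavelength Ca2+ indicator calibration (one-site binding)."""

    name: str
    kd_uM: float
    f_min: float
    f_max: float

    def __post_init__(self) -> None:
        if self.kd_uM <= 0:
            raise ValueError("indicator Kd must be positive")
        if self.f_max <= self.f_min:
            raise ValueError("f_max must exceed f_min")

    def fluorescence(self, free_uM: np.ndarray) -> np.ndarray:
        x = np.asarray(free_uM, dtype=float) / self.kd_uM
        return (self.f_min + self.f_max * x) / (1.0 + x)


@dataclass
class FuraCalibration:
    """Ratiometric (Grynkiewicz) calibration constants for fura-2."""

    kd_nM: float = 224.0
    r_min: float = 0.5
    r_max: float = 6.0
    beta: float = 5.0  # F380max / F380min
    f380_max: float = 1000.0

    def __post_init__(self) -> None:
        if self.kd_nM <= 0 or self.beta <= 0:
            raise ValueError("Kd and beta must be positive")
        if self.r_max <= self.r_min:
            raise ValueError("r_max must exceed r_min")

    def ratio(self, ca_nM: np.ndarray) -> np.ndarray:
        """Forward map [Ca2+] (nM) -> fura-2 ratio."""
        x = np.asarray(ca_nM, dtype=float) / (self.kd_nM * self.beta)
        return (self.r_min + self.r_max * x) / (1.0 + x)

    def f380(self, ca_nM: np.ndarray) -> np.ndarray:
        """380 nm intensity falls from F380max to F380max/beta with Ca2+."""
        x = np.asarray(ca_nM, dtype=float) / (self.kd_nM * self.beta)
        return self.f380_max * (1.0 + x / self.beta) / (1.0 + x)


FLUO4 = Indicator("Fluo-4", kd_uM=0.345, f_min=50.0, f_max=5000.0)
FLUO4FF = Indicator("Fluo4-FF", kd_uM=9.7, f_min=50.0, f_max=5000.0)
EGTA_KD_APP_UM = 0.15  # apparent Kd at pH 7.2, room temperature


@dataclass
class FluxModel:
    """Ground-truth model for an isolated-mitochondria uptake assay.

    ``true_G`` is the whole-membrane chord conductance per mg protein.
    The matrix free [Ca2+] is held constant (matrix buffering dominates
    over the 35 s assay) and the membrane potential is clamped, so the
    uptake flux follows I = G (psi - E_Ca) with E_Ca drifting only through
    the declining extramitochondrial free [Ca2+].
    """

    true_G_nS_mg: float = 2.0e4
    psi_m_mV: float = -160.0
    ca_matrix_nM: float = 200.0
    buffers: list[Buffer] = field(default_factory=list)
    indicator: Indicator = field(default_factory=lambda: FLUO4)
    protein_mg_ml: float = 0.5
    volume_ul: float = 200.0
    temperature_K: float = 298.15
    matrix_fura: FuraCalibration = field(default_factory=FuraCalibration)
    noise_sd: float = 2.0  # photometric noise, a.u. (indicator full scale 5000)

    def __post_init__(self) -> None:
        if self.protein_mg_ml <= 0 or self.volume_ul <= 0:
            raise ValueError("protein and volume must be positive")
        if any(b.total_uM < 0 for b in self.buffers):
            raise ValueError("buffer totals must be non-negative")


def protocol_buffers(ca_added_uM: float) -> tuple[list[Buffer], Indicator]:
    """Assay composition by protocol.

    At or below 3 µM added Ca2+ (protocol 1), Fluo-4 (3 µM) is the sole
    significant buffer and also the indicator. Above 3 µM (protocol 2)
    the mitochondria carry over EGTA from their resuspension — diluted
    ~20-fold into the well, i.e. ~2 µM — and the low-affinity Fluo4-FF
    (1 µM) reports the µM-range free Ca2+.
    """
    if ca_added_uM <= 3.0:
        bufs = [Buffer("Fluo-4", 3.0, FLUO4.kd_uM)]
        return bufs, FLUO4
    bufs = [
        Buffer("EGTA", 2.0, EGTA_KD_APP_UM),
        Buffer("Fluo4-FF", 1.0, FLUO4FF.kd_uM),
    ]
    return bufs, FLUO4FF


def default_flux_model(ca_added_uM: float = 10.0, **kwargs) -> FluxModel:
    bufs, ind = protocol_buffers(ca_added_uM)
    kwargs.setdefault("buffers", bufs)
    kwargs.setdefault("indicator", ind)
    return FluxModel(**kwargs)


def _free_from_total(total_uM: float, buffers: Sequence[Buffer]) -> float:
    """Positive root of the mass-action equilibrium (Newton-safe bisection)."""
    if total_uM <= 0:
        return 0.0
    lo, hi = 0.0, total_uM

    def g(free: float) -> float:
        bound = sum(b.total_uM * free / (b.kd_uM + free) for b in buffers)
        return free + bound - total_uM

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _nernst_mV(ca_out_uM: float, ca_in_nM: float, temperature_K: float) -> float:
    rt_over_zf = 1e3 * GAS_R * temperature_K / (2.0 * FARADAY)  # mV
    return rt_over_zf * np.log(ca_out_uM * 1e3 / ca_in_nM)


def simulate_flux_assay(
    model: FluxModel,
    ca_added_uM: float,
    duration_s: float = 35.0,
    dt_s: float = 0.05,
    seed: int = 0,
) -> tuple[FluxAssayRecord, dict]:
    """Simulate a Ca2+-uptake assay at one added [Ca2+].

    Forward-Euler integration of the chord-conductance flux: at each step
    the extramitochondrial free [Ca2+] is solved from the buffer
    equilibrium, the Nernst potential computed against the (fixed) matrix
    free [Ca2+], and uptake I = G (psi - E) removes total Ca2+ from the
    bath compartment. Conservation (free + bound + cumulative uptake =
    added) holds to solver precision at every sample.

    Returns the plate-reader record plus a ground-truth dict with the
    noise-free free/total/uptake trajectories.
    """
    if ca_added_uM < 0:
        raise ValueError("ca_added_uM must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt_s)) + 1
    time = np.arange(n) * dt_s

    mg_total = model.protein_mg_ml * model.volume_ul * 1e-3  # mg in the well
    vol_L = model.volume_ul * 1e-6

    total = np.empty(n)
    free = np.empty(n)
    uptake = np.empty(n)  # cumulative, µM referred to bath volume
    total[0] = ca_added_uM
    uptake[0] = 0.0
    zero_flux_warned = False
    for i in range(n):
        free[i] = _free_from_total(total[i], model.buffers)
        if i == n - 1:
            break
        if free[i] <= 0:
            j_uM_s = 0.0
        else:
            e_ca = _nernst_mV(free[i], model.ca_matrix_nM, model.temperature_K)
            drive = model.psi_m_mV - e_ca
            if drive == 0.0 and not zero_flux_warned:
                import warnings

                warnings.warn("membrane potential equals E_Ca: zero-flux record")
                zero_flux_warned = True
            # I (pA/mg) = G(nS/mg) * drive(mV); J (mol/s/mg) = -I/(zF)
            i_pA_mg = model.true_G_nS_mg * drive
            j_mol_s_mg = -i_pA_mg * 1e-12 / (2.0 * FARADAY)
            j_uM_s = j_mol_s_mg * mg_total / vol_L * 1e6
            j_uM_s = min(j_uM_s, total[i] / dt_s) if j_uM_s > 0 else 0.0
        uptake[i + 1] = uptake[i] + j_uM_s * dt_s
        total[i + 1] = ca_added_uM - uptake[i + 1]

    f_ca = model.indicator.fluorescence(free)
    fura = model.matrix_fura
    f380 = np.full(n, fura.f380(model.ca_matrix_nM))
    f340 = fura.ratio(model.ca_matrix_nM) * f380
    # TMRM ratio channels encode psi through a linear monotone map; the
    # analysis treats the map as a pluggable calibration.
    ratio = 1.0 + (-model.psi_m_mV) / 100.0
    num = np.full(n, 1000.0 * ratio)
    den = np.full(n, 1000.0)
    if model.noise_sd > 0:
        f_ca = f_ca + rng.normal(0, model.noise_sd, n)
        f340 = f340 + rng.normal(0, model.noise_sd, n)
        f380 = f380 + rng.normal(0, model.noise_sd, n)
        num = num + rng.normal(0, model.noise_sd, n)
        den = den + rng.normal(0, model.noise_sd, n)
    rec = FluxAssayRecord(
        time=time,
        f_ca_ex=f_ca,
        f_fura340=f340,
        f_fura380=f380,
        f_tmrm_num=num,
        f_tmrm_den=den,
        meta={
            "ca_added_uM": ca_added_uM,
            "protein_mg_ml": model.protein_mg_ml,
            "volume_ul": model.volume_ul,
            "psi_m_mV": model.psi_m_mV,
            "indicator": model.indicator.name,
            "buffers": [(b.name, b.total_uM, b.kd_uM) for b in model.buffers],
            "temperature_K": model.temperature_K,
        },
    )
    truth = {
        "free_uM": free,
        "total_uM": total,
        "uptake_uM": uptake,
        "true_G_nS_mg": model.true_G_nS_mg,
    }
    return rec, truth


# --------------------------------------------------------------------------
# Time-lapse imaging of intact cells
# --------------------------------------------------------------------------


@dataclass
class ImagingModel:
    """Ground truth for a thapsigargin-evoked imaging experiment.

    The cytosolic [Ca2+] follows ``cyto_ramp`` (nM as a function of time);
    the mitochondrial signal stays at baseline until ``onset_time`` and
    then rises as gain*(1 - exp(-(t-onset)/tau)). ``threshold_ca`` is the
    cytosolic concentration at the onset; the default factory keeps the
    two consistent by construction.
    """

    onset_time: float
    threshold_ca_nM: float
    cyto_ramp: Callable[[np.ndarray], np.ndarray]
    stimulus_time: float = 120.0
    mito_gain: float = 1.5
    mito_tau: float = 60.0
    frame_interval: float = 3.0
    noise_sd_fura: float = 4.0  # counts, on ROI-averaged intensities ~500-1000
    noise_sd_cepia: float = 2.0  # counts, on baseline ~500
    fura: FuraCalibration = field(default_factory=FuraCalibration)
    cepia_f0: float = 500.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


def default_imaging_model(
    threshold_ca_nM: float = 400.0,
    resting_ca_nM: float = 100.0,
    stimulus_time: float = 120.0,
    rise_rate_nM_s: float = 5.0,
    plateau_nM: float = 1000.0,
    **kwargs,
) -> ImagingModel:
    """Thapsigargin scenario: resting [Ca2+]i until the stimulus, then a
    linear rise (default 5 nM/s) saturating at ``plateau_nM``. The onset
    time is where the ramp crosses ``threshold_ca_nM`` (the stimulus time
    itself if the threshold is at or below resting, as in MICU1-KO)."""

    def ramp(t):
        t = np.asarray(t, dtype=float)
        ca = resting_ca_nM + rise_rate_nM_s * np.clip(t - stimulus_time, 0.0, None)
        return np.minimum(ca, plateau_nM)

    if threshold_ca_nM <= resting_ca_nM:
        onset = stimulus_time
        threshold_ca_nM = resting_ca_nM
    else:
        onset = stimulus_time + (threshold_ca_nM - resting_ca_nM) / rise_rate_nM_s
    return ImagingModel(
        onset_time=onset,
        threshold_ca_nM=threshold_ca_nM,
        cyto_ramp=ramp,
        stimulus_time=stimulus_time,
        **kwargs,
    )


def simulate_imaging(
    model: ImagingModel,
    duration: float = 720.0,
    seed: int = 0,
    cell_id: str = "cell0",
    dish_id: str = "dish0",
    genotype: str = "WT",
) -> ImagingTrace:
    """Simulate one cell's paired fura-2 / Cepia trace."""
    if not (0.0 <= model.onset_time <= duration):
        raise ValueError("onset_time must lie within the recording")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration / model.frame_interval)) + 1
    t = np.arange(n) * model.frame_interval
    ca = np.asarray(model.cyto_ramp(t), dtype=float)

    f380 = model.fura.f380(ca)
    f340 = model.fura.ratio(ca) * f380

    rel = np.clip(t - model.onset_time, 0.0, None)
    ff0 = 1.0 + model.mito_gain * (1.0 - np.exp(-rel / model.mito_tau))
    ff0 = np.where(t >= model.onset_time, ff0, 1.0)
    f_cepia = model.cepia_f0 * ff0

    if model.noise_sd_fura > 0:
        f340 = f340 + rng.normal(0, model.noise_sd_fura, n)
        f380 = f380 + rng.normal(0, model.noise_sd_fura, n)
    if model.noise_sd_cepia > 0:
        f_cepia = f_cepia + rng.normal(0, model.noise_sd_cepia, n)
    return ImagingTrace(
        time=t,
        f340=np.clip(f340, 0, None),
        f380=np.clip(f380, 0, None),
        f_cepia=np.clip(f_cepia, 0, None),
        cell_id=cell_id,
        dish_id=dish_id,
        stimulus_time=model.stimulus_time,
        genotype=genotype,
    )
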