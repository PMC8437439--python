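"""Whole-membrane Ca2+ conductance from isolated-mitochondria assays.

The chain of inference: calibrate the extramitochondrial Ca2+ indicator,
invert the buffer equilibrium to total Ca2+, take the slope of total
[Ca2+] over the first 20 s as the uptake flux J, convert to current with
the Faraday constant (z = 2), compute the Nernst reversal potential from
the free Ca2+ on both membrane faces, and divide by the driving force:

    I = G (dPsi_m - E_Ca)   =>   G = I / (dPsi_m - E_Ca)

Sign conventions: J > 0 is uptake into mitochondria; I = -z F J so that
inward current is negative; with the matrix negative the driving force
is negative and G comes out positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .records import FluxAssayRecord
from .synthetic import Buffer, FARADAY, GAS_R, FuraCalibration, Indicator

__all__ = [
    "ConductancePoint",
    "calibrate_fura",
    "calibrate_single_wavelength",
    "solve_free_ca",
    "estimate_flux",
    "nernst_eca",
    "chord_conductance",
    "analyze_flux_assay",
    "g_vs_ca_curve",
    "depolarization_index",
]

Z_CA = 2


@dataclass
class ConductancePoint:
    """One (J, I, E_Ca, dPsi_m, G) inference at a single bath [Ca2+]."""

    ca_i_free_uM: float
    ca_m_free_nM: float
    psi_m_mV: float
    j_mol_s_mg: float  # uptake-positive flux
    i_A_mg: float  # signed current, inward negative
    e_ca_mV: float
    g_S_mg: float
    genotype: str = ""

    def __post_init__(self) -> None:
        drive = self.psi_m_mV - self.e_ca_mV
        if drive != 0 and not np.isclose(
            self.g_S_mg, self.i_A_mg / (drive * 1e-3), rtol=1e-9, atol=0
        ):
            raise ValueError("G must equal I / (psi_m - E_Ca)")

    @property
    def g_nS_mg(self) -> float:
        return self.g_S_mg * 1e9


def calibrate_fura(ratio, cal: FuraCalibration):
    """Free [Ca2+] (nM) from a fura-2 ratio via the ratiometric
    (Grynkiewicz) equation [Ca] = Kd * (R - Rmin)/(Rmax - R) * beta.

    Ratios at or above Rmax raise (dye saturated); ratios below Rmin are
    clamped to Rmin with a warning (negative concentrations have no
    meaning; sub-Rmin readings are noise excursions).
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r >= cal.r_max):
        raise ValueError("ratio at or above Rmax: fura-2 saturated")
    if np.any(r < cal.r_min):
        import warnings

        warnings.warn("ratio below Rmin clamped to Rmin (zero free Ca2+)")
        r = np.maximum(r, cal.r_min)
    out = cal.kd_nM * (r - cal.r_min) / (cal.r_max - r) * cal.beta
    return float(out) if np.isscalar(ratio) else out


def calibrate_single_wavelength(f, cal: Indicator):
    """Free [Ca2+] (µM) from a single-wavelength dye:
    [Ca] = Kd * (F - Fmin)/(Fmax - F)."""
    x = np.asarray(f, dtype=float)
    if np.any(x >= cal.f_max):
        raise ValueError("fluorescence at or above Fmax: indicator saturated")
    out = cal.kd_uM * np.maximum(x - cal.f_min, 0.0) / (cal.f_max - x)
    return float(out) if np.isscalar(f) else out


def solve_free_ca(
    total_ca_uM: float, buffers: Sequence[Buffer]
) -> tuple[float, dict[str, float]]:
    """Free [Ca2+] and per-buffer bound amounts from total Ca2+.

    Solves free + sum_i B_i free/(Kd_i + free) = total by bracketed root
    finding on [0, total]; conservation holds to 1e-9 relative.
    """
    if total_ca_uM < 0:
        raise ValueError("total Ca2+ must be non-negative")
    if total_ca_uM == 0 or not buffers:
        bound = {b.name: 0.0 for b in buffers}
        return float(total_ca_uM), bound

    def g(free: float) -> float:
        return (
            free
            + sum(b.total_uM * free / (b.kd_uM + free) for b in buffers)
            - total_ca_uM
        )

    if g(0.0) > 0 or g(total_ca_uM) < 0:
        raise ValueError("equilibrium has no bracket on [0, total]")
    free = optimize.brentq(g, 0.0, total_ca_uM, xtol=1e-18, rtol=1e-15)
    bound = {b.name: b.total_uM * free / (b.kd_uM + free) for b in buffers}
    return float(free), bound


def total_from_free(free_uM, buffers: Sequence[Buffer]):
    """Forward map free -> total (free plus all bound species)."""
    free = np.asarray(free_uM, dtype=float)
    total = free.copy()
    for b in buffers:
        total = total + b.total_uM * free / (b.kd_uM + free)
    return total


def estimate_flux(
    time_s: np.ndarray,
    total_ca_uM: np.ndarray,
    window_s: float = 20.0,
    volume_ul: float = 200.0,
    protein_mg_ml: float = 0.5,
) -> tuple[float, float]:
    """Uptake flux J (mol s^-1 mg^-1) from the total extramitochondrial
    [Ca2+] trace: ordinary least-squares slope over the first ``window_s``
    seconds, scaled by well volume and protein. Uptake (declining trace)
    gives J > 0. Returns (J, standard error of J)."""
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(total_ca_uM, dtype=float)
    sel = t - t[0] <= window_s
    if sel.sum() < 4:
        raise ValueError("flux window must contain at least 4 samples")
    res = sps.linregress(t[sel], y[sel])
    mg = protein_mg_ml * volume_ul * 1e-3
    vol_L = volume_ul * 1e-6
    scale = 1e-6 * vol_L / mg  # µM/s -> mol/s/mg
    return -res.slope * scale, res.stderr * scale


def nernst_eca(
    ca_i_free_uM: float, ca_m_free_nM: float, temperature_K: float = 298.15
) -> float:
    """Nernst reversal potential for Ca2+ in mV (z = 2).

    E = (RT / zF) ln([Ca]_cyto / [Ca]_matrix); with the package voltage
    convention psi_m - E is the driving force for influx.
    """
    if ca_i_free_uM <= 0 or ca_m_free_nM <= 0:
        raise ValueError("free concentrations must be positive")
    rt_over_zf_mV = 1e3 * GAS_R * temperature_K / (Z_CA * FARADAY)
    return rt_over_zf_mV * float(np.log(ca_i_free_uM * 1e3 / ca_m_free_nM))


def chord_conductance(
    j_mol_s_mg: float, psi_m_mV: float, e_ca_mV: float
) -> tuple[float, float]:
    """Convert flux to current and chord conductance.

    I = -z F J (A/mg, inward negative for uptake-positive J);
    G = I / (psi_m - E_Ca) in S/mg. A driving force below 1 mV in
    magnitude is rejected as undefined.
    """
    drive_mV = psi_m_mV - e_ca_mV
    if abs(drive_mV) < 1.0:
        raise ValueError("driving force below 1 mV: conductance undefined")
    i_A_mg = -Z_CA * FARADAY * j_mol_s_mg
    g_S_mg = i_A_mg / (drive_mV * 1e-3)
    return i_A_mg, g_S_mg


def analyze_flux_assay(
    rec: FluxAssayRecord,
    indicator: Indicator,
    buffers: Sequence[Buffer],
    matrix_fura: FuraCalibration | None = None,
    psi_m_mV: float | None = None,
    tmrm_to_mV: Callable[[float], float] | None = None,
    window_s: float = 20.0,
    genotype: str = "",
) -> ConductancePoint:
    """Full inference for one assay record.

    The membrane potential comes either from ``psi_m_mV`` directly, a
    user-supplied monotone TMRM-ratio calibration ``tmrm_to_mV``, or the
    record's metadata, in that order of precedence.
    """
    matrix_fura = matrix_fura or FuraCalibration()
    free = calibrate_single_wavelength(rec.f_ca_ex, indicator)
    total = total_from_free(free, buffers)
    volume_ul = float(rec.meta.get("volume_ul", 200.0))
    protein = float(rec.meta.get("protein_mg_ml", 0.5))
    j, _ = estimate_flux(
        rec.time, total, window_s=window_s, volume_ul=volume_ul,
        protein_mg_ml=protein,
    )
    sel = rec.time - rec.time[0] <= window_s
    free_mid = float(np.mean(free[sel]))
    fura_ratio = rec.f_fura340[sel] / rec.f_fura380[sel]
    ca_m_nM = float(np.mean(calibrate_fura(fura_ratio, matrix_fura)))
    if psi_m_mV is None:
        if tmrm_to_mV is not None:
            psi_m_mV = float(tmrm_to_mV(float(np.mean(rec.tmrm_ratio[sel]))))
        elif "psi_m_mV" in rec.meta:
            psi_m_mV = float(rec.meta["psi_m_mV"])
        else:
            raise ValueError(
                "membrane potential unavailable: pass psi_m_mV or tmrm_to_mV"
            )
    temperature = float(rec.meta.get("temperature_K", 298.15))
    e_ca = nernst_eca(free_mid, ca_m_nM, temperature)
    i_A_mg, g_S_mg = chord_conductance(j, psi_m_mV, e_ca)
    return ConductancePoint(
        ca_i_free_uM=free_mid,
        ca_m_free_nM=ca_m_nM,
        psi_m_mV=psi_m_mV,
        j_mol_s_mg=j,
        i_A_mg=i_A_mg,
        e_ca_mV=e_ca,
        g_S_mg=g_S_mg,
        genotype=genotype,
    )


def g_vs_ca_curve(
    points: Sequence[ConductancePoint],
    bin_edges_uM: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Group conductance points by genotype and [Ca2+]i bin.

    Returns a table with mean +/- SEM of G per (genotype, bin); the
    KO-over-WT crossover (KO above WT at low [Ca2+]i, below at high) can
    be read off directly.
    """
    if not points:
        raise ValueError("no conductance points")
    df = pd.DataFrame(
        {
            "genotype": [p.genotype for p in points],
            "ca_i_uM": [p.ca_i_free_uM for p in points],
            "g_nS_mg": [p.g_nS_mg for p in points],
        }
    )
    if bin_edges_uM is None:
        bin_edges_uM = [0, 0.5, 1, 2, 3, 5, 8, 12, 18, 25, np.inf]
    df["ca_bin"] = pd.cut(df["ca_i_uM"], bin_edges_uM)
    out = (
        df.groupby(["genotype", "ca_bin"], observed=True)["g_nS_mg"]
        .agg(mean="mean", sem=lambda s: s.sem() if len(s) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out


def depolarization_index(
    time_s: np.ndarray,
    tmrm_ratio: np.ndarray,
    event_time_s: float,
    fccp_time_s: float,
    fccp_ratio: np.ndarray | None = None,
    window_s: float = 300.0,
) -> float:
    """Depolarization caused by an injection, as percent of full FCCP
    depolarization: 100 * delta(event) / delta(FCCP), each delta being the
    TMRM-ratio change over the 5-min post-injection window. The FCCP
    reference comes from ``fccp_ratio`` (a parallel recording on the same
    time base) or, if omitted, from a later FCCP injection into the same
    trace."""
    t = np.asarray(time_s, dtype=float)

    def delta(r: np.ndarray, t0: float) -> float:
        pre = r[t < t0]
        post = r[(t >= t0) & (t <= t0 + window_s)]
        if pre.size == 0 or post.size == 0:
            raise ValueError("injection window outside the recording")
        return float(post[-1] - pre[-1])

    r_event = np.asarray(tmrm_ratio, dtype=float)
    r_fccp = r_event if fccp_ratio is None else np.asarray(fccp_ratio, dtype=float)
    d_event = delta(r_event, event_time_s)
    d_fccp = delta(r_fccp, fccp_time_s)
    if d_fccp == 0:
        raise ZeroDivisionError("FCCP produced no ratio change")
    return 100.0 * d_event / d_fccp
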