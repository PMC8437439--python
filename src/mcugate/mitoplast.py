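"""Whole-mitoplast current metrics and the block/kinetics fits.

Operations on voltage-ramp sweeps: read currents and densities at stated
voltages, leak/control subtraction, per-mitoplast current ratios, Hill
fits of Mg2+ inhibition, one-site Ca2+ block of the Na+ current,
single-exponential activation/deactivation kinetics after fast solution
exchange, and the inward-rectification index |I(+80)| / |I(-160)|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .records import RampSweep

__all__ = [
    "CurrentMetrics",
    "HillFit",
    "KineticsFit",
    "EDGE_EXCLUSION_S",
    "current_at_voltage",
    "subtract_control",
    "ramp_metrics",
    "paired_ratio",
    "fit_hill_inhibition",
    "fit_ca_block_of_ina",
    "fit_exponential_kinetics",
    "rectification_index",
]

# ramp segment trimmed at either end to avoid capacitance transients
EDGE_EXCLUSION_S = 0.002
# averaging half-window around the stated measurement voltage
VOLTAGE_HALF_WINDOW_MV = 2.0


@dataclass
class CurrentMetrics:
    """Per-mitoplast measurements extracted from one or more sweeps."""

    density_at: dict[float, float] = field(default_factory=dict)  # mV -> pA/pF
    current_at: dict[float, float] = field(default_factory=dict)  # mV -> pA
    capacitance: float = np.nan
    condition: dict = field(default_factory=dict)


@dataclass
class HillFit:
    """Hill inhibition fit f(x) = 1 / (1 + (x/IC50)^nH), f(0) fixed at 1."""

    ic50: float
    n_h: float
    ic50_se: float
    n_h_se: float
    residual_norm: float
    warning: str = ""

    def __post_init__(self) -> None:
        if self.ic50 <= 0 or self.n_h <= 0:
            raise ValueError("IC50 and n_H must be positive")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 1.0 / (1.0 + (x / self.ic50) ** self.n_h)


@dataclass
class KineticsFit:
    """Single-exponential fit of a current transient."""

    tau: float  # same unit as the input time base
    amplitude: float
    baseline: float
    window: tuple[float, float]
    direction: str = "activation"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _trimmed(sweep: RampSweep) -> tuple[np.ndarray, np.ndarray]:
    t = sweep.time
    keep = (t >= t[0] + EDGE_EXCLUSION_S) & (t <= t[-1] - EDGE_EXCLUSION_S)
    if keep.sum() < 2:
        keep = np.ones_like(t, dtype=bool)
    return sweep.voltage[keep], sweep.current[keep]


def current_at_voltage(sweep: RampSweep, v: float) -> tuple[float, float]:
    """Current (pA) and density (pA/pF) at voltage ``v``.

    The reading averages the ramp segment within +/-2 mV of ``v``; if the
    window contains no sample the value is linearly interpolated.
    """
    vmin_full, vmax_full = sweep.voltage.min(), sweep.voltage.max()
    if not (vmin_full <= v <= vmax_full):
        raise ValueError(
            f"voltage {v} mV outside the ramp range [{vmin_full}, {vmax_full}]"
        )
    volts, curr = _trimmed(sweep)
    sel = np.abs(volts - v) <= VOLTAGE_HALF_WINDOW_MV
    if sel.sum() >= 3:
        # local line through the window, evaluated at v: averages noise,
        # exact for a locally linear I-V, unbiased at clipped edge windows
        slope, intercept = np.polyfit(volts[sel], curr[sel], 1)
        i = float(slope * v + intercept)
    else:
        order = np.argsort(volts)
        i = float(np.interp(v, volts[order], curr[order]))
    return i, i / sweep.capacitance


def subtract_control(sweep: RampSweep, control: RampSweep) -> RampSweep:
    """Pointwise control (leak) subtraction after voltage alignment."""
    if sweep.voltage.size != control.voltage.size or not np.allclose(
        sweep.voltage, control.voltage, atol=1e-9
    ):
        raise ValueError("sweeps were recorded with different voltage protocols")
    return RampSweep(
        time=sweep.time,
        voltage=sweep.voltage,
        current=sweep.current - control.current,
        capacitance=sweep.capacitance,
        condition={**sweep.condition, "control_subtracted": True},
    )


def ramp_metrics(sweep: RampSweep, voltages: Sequence[float] = (-160.0, -80.0, 80.0)) -> CurrentMetrics:
    """Standard per-sweep readings (defaults per the figure conventions:
    -160 mV for Ca2+/Mn2+, -80 mV for Na+, +80 mV for the outward check)."""
    m = CurrentMetrics(capacitance=sweep.capacitance, condition=dict(sweep.condition))
    for v in voltages:
        i, d = current_at_voltage(sweep, v)
        m.current_at[v] = i
        m.density_at[v] = d
    return m


def paired_ratio(
    numerator: RampSweep,
    denominator: RampSweep,
    v_num: float = -160.0,
    v_den: float = -80.0,
) -> float:
    """Ratio of stated-voltage currents from the same mitoplast.

    E.g. I_Ca(-160)/I_Na(-80) or I_Mn(-160)/I_Ca(-160). Uses magnitudes so
    the ratio is positive for same-sign inward currents, and is invariant
    to a common gain on both sweeps.
    """
    i_num, _ = current_at_voltage(numerator, v_num)
    i_den, _ = current_at_voltage(denominator, v_den)
    if i_den == 0:
        raise ZeroDivisionError("denominator current is zero")
    return abs(i_num) / abs(i_den)


def _fit_hill(conc: np.ndarray, resp: np.ndarray, fix_n_h: float | None, seed: int):
    """Seeded multi-start least squares for the Hill inhibition curve."""
    rng = np.random.default_rng(seed)
    pos = conc[conc > 0]
    guess_ic50 = float(np.median(pos)) if pos.size else 1.0

    if fix_n_h is None:
        def f(x, ic50, n_h):
            return 1.0 / (1.0 + (np.maximum(x, 0) / ic50) ** n_h)
        p0s = [(guess_ic50, 1.0)] + [
            (guess_ic50 * 10 ** rng.uniform(-1, 1), rng.uniform(0.5, 2.0))
            for _ in range(4)
        ]
        bounds = ([1e-12, 1e-3], [np.inf, 20.0])
    else:
        def f(x, ic50):
            return 1.0 / (1.0 + np.maximum(x, 0) / ic50)
        p0s = [(guess_ic50,)] + [
            (guess_ic50 * 10 ** rng.uniform(-1, 1),) for _ in range(4)
        ]
        bounds = ([1e-12], [np.inf])

    best = None
    for p0 in p0s:
        try:
            popt, pcov = curve_fit(
                f, conc, resp, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((f(conc, *popt) - resp) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from all starts")
    return best


def fit_hill_inhibition(
    points: Sequence[tuple[float, float]],
    fix_n_h: float | None = None,
    seed: int = 0,
) -> HillFit:
    """Fit normalized dose-inhibition data to f(x) = 1/(1 + (x/IC50)^nH).

    ``points`` are (concentration, normalized current) pairs including the
    zero-concentration reference; f(0) = 1 is fixed by the functional
    form, matching normalization to the block-free current. Data that are
    non-monotone beyond ~3x the residual scatter are flagged, not fatal.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (concentration, response) points")
    if not np.any(pts[:, 0] == 0):
        raise ValueError("points must include the zero-concentration reference")
    conc, resp = pts[:, 0], pts[:, 1]
    popt, pcov, rss = _fit_hill(conc, resp, fix_n_h, seed)
    se = np.sqrt(np.diag(pcov))
    if fix_n_h is None:
        ic50, n_h = popt
        ic50_se, n_h_se = se
    else:
        ic50, n_h = popt[0], fix_n_h
        ic50_se, n_h_se = se[0], 0.0

    warning = ""
    order = np.argsort(conc)
    increments = np.diff(resp[order])
    # responses are normalized to the block-free current, so an upward
    # step of more than 10 % of that scale is beyond plausible noise
    if np.any(increments > 0.1):
        warning = "non-monotone dose-response beyond noise tolerance"
    return HillFit(
        ic50=float(ic50),
        n_h=float(n_h),
        ic50_se=float(ic50_se),
        n_h_se=float(n_h_se),
        residual_norm=float(np.sqrt(rss)),
        warning=warning,
    )


def fit_ca_block_of_ina(
    points: Sequence[tuple[float, float]], seed: int = 0
) -> HillFit:
    """One-site block of the Na+ current by cytosolic Ca2+.

    f([Ca]) = 1/(1 + [Ca]/Kd); the fitted ``ic50`` is the Kd (nM when
    concentrations are given in nM).
    """
    return fit_hill_inhibition(points, fix_n_h=1.0, seed=seed)


def fit_exponential_kinetics(
    time: np.ndarray,
    current: np.ndarray,
    direction: str = "activation",
    normalize: bool = False,
) -> KineticsFit:
    """Single-exponential fit of the post-switch current transient.

    activation: I(t) = baseline + A * (1 - exp(-t/tau))
    deactivation: I(t) = baseline + A * exp(-t/tau)

    ``time`` is taken relative to its first sample. With ``normalize``
    the trace is scaled to its maximal amplitude before fitting (the
    kinetics are unchanged; only A is). The trace must span at least
    three sample intervals and have non-zero amplitude.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(current, dtype=float)
    if t.size != y.size or t.size < 4:
        raise ValueError("need a time/current window of at least 4 samples")
    dt = np.median(np.diff(t))
    if t[-1] - t[0] < 3 * dt:
        raise ValueError("fit window shorter than 3 sample intervals")
    t = t - t[0]
    amp0 = y[-1] - y[0] if direction == "activation" else y[0] - y[-1]
    if abs(amp0) < 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("zero-amplitude transient: nothing to fit")
    if normalize:
        y = y / np.abs(y).max()
        amp0 = y[-1] - y[0] if direction == "activation" else y[0] - y[-1]

    tau0 = (t[-1] - t[0]) / 5.0
    if direction == "activation":
        def f(tt, tau, a, b):
            return b + a * (1.0 - np.exp(-tt / tau))
        p0 = (tau0, amp0, y[0])
    elif direction == "deactivation":
        def f(tt, tau, a, b):
            return b + a * np.exp(-tt / tau)
        p0 = (tau0, amp0, y[-1])
    else:
        raise ValueError("direction must be 'activation' or 'deactivation'")
    popt, _ = curve_fit(
        f, t, y, p0=p0,
        bounds=([dt * 1e-6, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000, xtol=1e-14, ftol=1e-14,
    )
    return KineticsFit(
        tau=float(popt[0]),
        amplitude=float(popt[1]),
        baseline=float(popt[2]),
        window=(float(time[0]), float(time[-1])),
        direction=direction,
    )


def rectification_index(
    sweep: RampSweep,
    v_out: float = 80.0,
    v_in: float = -160.0,
    half_window_mV: float = 5.0,
) -> float:
    """|I(+80 mV)| / |I(-160 mV)| for a sweep with matrix Ca2+ present.

    An inwardly rectifying channel gives an index near 0 even with a
    large outward driving force. Both readings are plain means over a
    +/-5 mV window (clipped to the ramp range): near-zero outward
    currents sit at the ramp edge where a fitted local line would
    amplify noise, and a wider average suppresses it instead.
    """
    volts, curr = _trimmed(sweep)

    def window_mean(v: float) -> float:
        sel = np.abs(volts - v) <= half_window_mV
        if not sel.any():
            raise ValueError(f"no samples within {half_window_mV} mV of {v} mV")
        return float(curr[sel].mean())

    i_out = window_mean(v_out)
    i_in = window_mean(v_in)
    if i_in == 0:
        raise ZeroDivisionError("no inward current to normalize against")
    return abs(i_out) / abs(i_in)
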