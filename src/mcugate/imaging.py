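"""Mitochondrial Ca2+-uptake onset detection in paired imaging traces.

The mitochondrial (Cepia) F/F0 trace is smoothed with a zero-phase
second-order Butterworth filter, and the upstroke frame is the earliest
point between the end of the baseline and the signal peak whose time
derivative exceeds 80 % of the maximal derivative in that interval. The
cytosolic threshold is the fura-2 reading at that frame, calibrated with
the ratiometric equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats as sps

from .flux import calibrate_fura
from .records import ImagingTrace
from .synthetic import FuraCalibration

__all__ = [
    "ThresholdResult",
    "normalize_f0",
    "zero_phase_butterworth",
    "select_cutoff",
    "detect_upstroke",
    "threshold_ca",
    "analyze_trace",
    "batch_thresholds",
]

DERIVATIVE_FRACTION = 0.8
FALLBACK_CUTOFF_HZ = 0.03  # for 3-s frame data


class NoUpstrokeError(RuntimeError):
    """Raised when no frame satisfies the derivative criterion."""


@dataclass
class ThresholdResult:
    upstroke_frame: int
    upstroke_time: float
    threshold_ca_nM: float
    filter_cutoff_used: float
    qc_flags: list[str] = field(default_factory=list)


def normalize_f0(series: np.ndarray, baseline_end_frame: int) -> np.ndarray:
    """F/F0: divide by the mean of the pre-stimulus baseline window."""
    y = np.asarray(series, dtype=float)
    if baseline_end_frame < 1 or baseline_end_frame > y.size:
        raise ValueError("baseline window must contain at least one frame")
    f0 = y[:baseline_end_frame].mean()
    if f0 <= 0:
        raise ValueError("baseline fluorescence must be positive")
    return y / f0


def zero_phase_butterworth(
    series: np.ndarray, cutoff_hz: float, frame_interval_s: float
) -> np.ndarray:
    """Forward-backward 2nd-order Butterworth low-pass (zero phase lag,
    unit DC gain)."""
    fs = 1.0 / frame_interval_s
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    y = np.asarray(series, dtype=float)
    sos = signal.butter(2, cutoff_hz, fs=fs, output="sos")
    # pad generously relative to the filter time constant so edge
    # transients die out; keeps the forward/backward result symmetric
    padlen = int(min(y.size - 1, max(9, 4 * fs / cutoff_hz)))
    return signal.sosfiltfilt(sos, y, padlen=padlen, padtype="even")


def select_cutoff(
    series: np.ndarray,
    frame_interval_s: float,
    candidates: Sequence[float] | None = None,
) -> float:
    """Residual-analysis cutoff selection.

    The residual RMS between raw and filtered traces is computed over a
    grid of cutoffs; at high cutoffs the residual is noise-dominated and
    ~linear in cutoff. That linear tail is extrapolated back to zero
    cutoff and the chosen cutoff is where the residual curve first drops
    to the extrapolated intercept — the classic signal-vs-noise
    compromise. Falls back to 0.03 Hz if the intersection is not bracketed.
    """
    y = np.asarray(series, dtype=float)
    fs = 1.0 / frame_interval_s
    nyq = fs / 2
    if candidates is None:
        candidates = np.linspace(0.05, 0.9, 30) * nyq
    candidates = np.asarray([c for c in candidates if 0 < c < nyq])
    if candidates.size < 4:
        return min(FALLBACK_CUTOFF_HZ, 0.9 * nyq)
    resid = np.array(
        [
            np.sqrt(np.mean((y - zero_phase_butterworth(y, c, frame_interval_s)) ** 2))
            for c in candidates
        ]
    )
    # linear fit to the top-third (noise-dominated) tail
    tail = candidates >= candidates[int(0.66 * candidates.size)]
    slope, intercept = np.polyfit(candidates[tail], resid[tail], 1)
    below = np.nonzero(resid <= intercept)[0]
    if intercept <= 0 or below.size == 0:
        return min(FALLBACK_CUTOFF_HZ, 0.9 * nyq)
    return float(candidates[below[0]])


def detect_upstroke(
    smoothed: np.ndarray,
    baseline_end_frame: int,
    stimulus_frame: int | None = None,
) -> tuple[int, list[str]]:
    """Earliest frame between baseline end and the global peak whose
    central-difference derivative exceeds 80 % of the maximal derivative
    in that interval. Returns (frame index, QC flags)."""
    y = np.asarray(smoothed, dtype=float)
    flags: list[str] = []
    peak = int(np.argmax(y))
    if stimulus_frame is not None and peak < stimulus_frame:
        flags.append("peak-before-stimulus")
    lo = max(baseline_end_frame, 1)
    hi = min(peak, y.size - 2)
    if hi <= lo:
        raise NoUpstrokeError("no interval between baseline end and peak")
    deriv = (y[2:] - y[:-2]) / 2.0  # central difference, edge frames excluded
    idx = np.arange(1, y.size - 1)
    sel = (idx >= lo) & (idx <= hi)
    d = deriv[sel]
    frames = idx[sel]
    dmax = d.max()
    if dmax <= 0:
        raise NoUpstrokeError("trace does not rise between baseline and peak")
    hits = np.nonzero(d >= DERIVATIVE_FRACTION * dmax)[0]
    if hits.size == 0:
        raise NoUpstrokeError("no frame exceeds the derivative criterion")
    frame = int(frames[hits[0]])
    if frame == lo:
        flags.append("criterion-at-boundary")
    return frame, flags


def threshold_ca(
    upstroke_frame: int,
    trace: ImagingTrace,
    calibration: FuraCalibration,
) -> float:
    """Cytosolic [Ca2+] (nM) at the upstroke frame, from the fura-2 ratio."""
    r = trace.ratio[upstroke_frame]
    return float(calibrate_fura(float(r), calibration))


def analyze_trace(
    trace: ImagingTrace,
    calibration: FuraCalibration | None = None,
    cutoff_hz: float | str = "auto",
) -> ThresholdResult:
    """Full per-cell analysis: F/F0, smoothing, upstroke, threshold."""
    calibration = calibration or FuraCalibration()
    dt = trace.frame_interval
    baseline_end = int(np.searchsorted(trace.time, trace.stimulus_time))
    baseline_end = max(baseline_end, 1)
    ff0 = normalize_f0(trace.f_cepia, baseline_end)
    if cutoff_hz == "auto":
        cutoff = select_cutoff(ff0, dt)
    else:
        cutoff = float(cutoff_hz)
    smooth = zero_phase_butterworth(ff0, cutoff, dt)
    frame, flags = detect_upstroke(smooth, baseline_end, stimulus_frame=baseline_end)
    r = trace.ratio[frame]
    if r >= calibration.r_max:
        flags.append("saturated-fura-ratio")
        ca = float("nan")
    else:
        ca = threshold_ca(frame, trace, calibration)
    return ThresholdResult(
        upstroke_frame=frame,
        upstroke_time=float(trace.time[frame]),
        threshold_ca_nM=ca,
        filter_cutoff_used=cutoff,
        qc_flags=flags,
    )


@dataclass
class BatchResult:
    dish_means: dict[str, dict[str, float]]  # genotype -> dish -> mean nM
    group_means: dict[str, float]
    group_sems: dict[str, float]
    anova_F: float
    anova_p: float
    tukey: object | None = None


def batch_thresholds(
    results: Sequence[tuple[str, str, float]],
) -> BatchResult:
    """Dish-first aggregation and one-way ANOVA across genotypes.

    ``results`` is a sequence of (genotype, dish_id, threshold_nM) per
    cell. Cell thresholds are averaged to dish level first; the ANOVA
    (with Tukey post-hoc when >= 2 groups of >= 2 dishes each) runs on
    dish means, mirroring per-dish statistics.
    """
    by: dict[str, dict[str, list[float]]] = {}
    for geno, dish, thr in results:
        if np.isfinite(thr):
            by.setdefault(geno, {}).setdefault(dish, []).append(thr)
    if not by:
        raise ValueError("no finite thresholds to aggregate")
    dish_means = {
        g: {d: float(np.mean(v)) for d, v in dishes.items()} for g, dishes in by.items()
    }
    groups = {g: np.array(list(d.values())) for g, d in dish_means.items()}
    gm = {g: float(v.mean()) for g, v in groups.items()}
    gs = {
        g: float(sps.sem(v)) if v.size > 1 else 0.0 for g, v in groups.items()
    }
    arrays = list(groups.values())
    if len(arrays) >= 2 and all(a.size >= 2 for a in arrays):
        if np.ptp(np.concatenate(arrays)) == 0:
            # identical dishes everywhere: no effect, by convention p = 1
            f_stat, p, tukey = 0.0, 1.0, None
        else:
            f_stat, p = sps.f_oneway(*arrays)
            tukey = sps.tukey_hsd(*arrays)
    else:
        f_stat, p, tukey = float("nan"), float("nan"), None
    return BatchResult(
        dish_means=dish_means,
        group_means=gm,
        group_sems=gs,
        anova_F=float(f_stat),
        anova_p=float(p),
        tukey=tukey,
    )
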