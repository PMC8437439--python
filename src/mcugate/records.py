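"""Typed containers for the four recording modalities.

All analysis modules operate on these containers; the synthetic generators
produce them and :mod:`mcugate.io` reads/writes them as annotated CSV.
Sign and voltage conventions are fixed package-wide: voltages are on the
matrix side of the inner membrane relative to the cytosolic side, and
currents flowing into the matrix are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "SingleChannelRecording",
    "RampSweep",
    "FluxAssayRecord",
    "ImagingTrace",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class SingleChannelRecording:
    """A sampled single-channel current trace with acquisition metadata.

    Parameters
    ----------
    samples : array of current values, pA
    sample_rate : acquisition rate, Hz
    filter_cutoff : low-pass cutoff applied during acquisition, Hz
    voltage : holding potential, mV (matrix relative to cytosol)
    permeant_ion : e.g. ``"Ca"`` or ``"Na"``
    genotype : e.g. ``"WT"`` or ``"MICU1-KO"``
    """

    samples: np.ndarray
    sample_rate: float
    filter_cutoff: float
    voltage: float
    permeant_ion: str = "Ca"
    genotype: str = "WT"

    def __post_init__(self) -> None:
        self.samples = _as_1d(self.samples, "samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.size < 2:
            raise ValueError("recording needs at least 2 samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class RampSweep:
    """A whole-mitoplast voltage-ramp sweep.

    ``condition`` carries the recording condition (permeant ion, bath
    [Ca2+]/[Mg2+]/[Mn2+], genotype) as a plain dict so sweeps from
    different protocols stay self-describing.
    """

    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    capacitance: float
    condition: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time, "time")
        self.voltage = _as_1d(self.voltage, "voltage")
        self.current = _as_1d(self.current, "current")
        if not (self.time.size == self.voltage.size == self.current.size):
            raise ValueError("time, voltage and current must have equal length")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")

    @property
    def density(self) -> np.ndarray:
        """Current density, pA/pF."""
        return self.current / self.capacitance


@dataclass
class FluxAssayRecord:
    """Multi-channel plate-reader time series from an uptake assay.

    Channels: extramitochondrial Ca2+ indicator (Fluo-4 or Fluo4-FF),
    matrix fura-2 pair, and a TMRM ratio pair reporting membrane potential.
    ``meta`` carries assay constants (protein, volume, protocol, known
    membrane potential if supplied directly).
    """

    time: np.ndarray
    f_ca_ex: np.ndarray
    f_fura340: np.ndarray
    f_fura380: np.ndarray
    f_tmrm_num: np.ndarray
    f_tmrm_den: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time, "time")
        n = self.time.size
        for name in ("f_ca_ex", "f_fura340", "f_fura380", "f_tmrm_num", "f_tmrm_den"):
            arr = _as_1d(getattr(self, name), name)
            if arr.size != n:
                raise ValueError(f"{name} length does not match time")
            setattr(self, name, arr)

    @property
    def tmrm_ratio(self) -> np.ndarray:
        return self.f_tmrm_num / self.f_tmrm_den


@dataclass
class ImagingTrace:
    """Paired cytosolic (fura-2) / mitochondrial (Cepia) ROI trace."""

    time: np.ndarray
    f340: np.ndarray
    f380: np.ndarray
    f_cepia: np.ndarray
    cell_id: str = "cell0"
    dish_id: str = "dish0"
    stimulus_time: float = 0.0
    genotype: str = "WT"

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time, "time")
        n = self.time.size
        for name in ("f340", "f380", "f_cepia"):
            arr = _as_1d(getattr(self, name), name)
            if arr.size != n:
                raise ValueError(f"{name} length does not match time")
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative intensities")
            setattr(self, name, arr)
        if n >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame interval must be constant")

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def ratio(self) -> np.ndarray:
        """Fura-2 ratio F340/F380."""
        return self.f340 / self.f380
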