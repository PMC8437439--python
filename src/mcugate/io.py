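"""Annotated-CSV readers/writers and pipeline configuration.

Trace files are plain CSV with ``# key=value`` metadata header lines
followed by a column-name row. Column names carry units. Four kinds are
defined:

==============  =======================================================
kind            columns
==============  =======================================================
single_channel  time_s, current_pA
ramp            time_s, voltage_mV, current_pA
flux            time_s, F_ca_ex, F_fura340, F_fura380, F_tmrm_num,
                F_tmrm_den
imaging         time_s, F340, F380, F_cepia
==============  =======================================================
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .records import FluxAssayRecord, ImagingTrace, RampSweep, SingleChannelRecording

__all__ = ["read_trace_csv", "write_trace_csv", "ParseError"]

_COLUMNS = {
    "single_channel": ["time_s", "current_pA"],
    "ramp": ["time_s", "voltage_mV", "current_pA"],
    "flux": ["time_s", "F_ca_ex", "F_fura340", "F_fura380", "F_tmrm_num", "F_tmrm_den"],
    "imaging": ["time_s", "F340", "F380", "F_cepia"],
}


class ParseError(ValueError):
    """A trace file failed validation."""


def _coerce(value: str) -> Any:
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.startswith(("{", "[")):
        try:
            return json.loads(value)
        except json.JSONDecodeError:
            pass
    return value


def _read_meta(path: Path) -> dict[str, Any]:
    meta: dict[str, Any] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = _coerce(value.strip())
    return meta


def read_trace_csv(path: str | Path, kind: str):
    """Read an annotated trace CSV into the module-appropriate record.

    Validates the header metadata, column names and strictly increasing
    time; NaNs or missing columns raise :class:`ParseError`.
    """
    path = Path(path)
    if kind not in _COLUMNS:
        raise ValueError(f"unknown trace kind {kind!r}")
    if not path.exists() or path.stat().st_size == 0:
        raise ParseError(f"{path}: file is missing or empty")
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: no data rows") from exc
    missing = [c for c in _COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df[_COLUMNS[kind]].isna().any().any():
        raise ParseError(f"{path}: NaN values in data columns")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ParseError(f"{path}: time column is not strictly increasing")

    if kind == "single_channel":
        return SingleChannelRecording(
            samples=df["current_pA"].to_numpy(),
            sample_rate=float(meta.get("sample_rate_Hz", 1.0 / np.median(np.diff(t)))),
            filter_cutoff=float(meta.get("filter_cutoff_Hz", np.nan)),
            voltage=float(meta.get("voltage_mV", np.nan)),
            permeant_ion=str(meta.get("permeant_ion", "Ca")),
            genotype=str(meta.get("genotype", "WT")),
        )
    if kind == "ramp":
        condition = {
            k: v
            for k, v in meta.items()
            if k not in ("capacitance_pF", "kind")
        }
        return RampSweep(
            time=t,
            voltage=df["voltage_mV"].to_numpy(),
            current=df["current_pA"].to_numpy(),
            capacitance=float(meta.get("capacitance_pF", np.nan)),
            condition=condition,
        )
    if kind == "flux":
        return FluxAssayRecord(
            time=t,
            f_ca_ex=df["F_ca_ex"].to_numpy(),
            f_fura340=df["F_fura340"].to_numpy(),
            f_fura380=df["F_fura380"].to_numpy(),
            f_tmrm_num=df["F_tmrm_num"].to_numpy(),
            f_tmrm_den=df["F_tmrm_den"].to_numpy(),
            meta={k: v for k, v in meta.items() if k != "kind"},
        )
    return ImagingTrace(
        time=t,
        f340=df["F340"].to_numpy(),
        f380=df["F380"].to_numpy(),
        f_cepia=df["F_cepia"].to_numpy(),
        cell_id=str(meta.get("cell_id", "cell0")),
        dish_id=str(meta.get("dish_id", "dish0")),
        stimulus_time=float(meta.get("stimulus_time_s", 0.0)),
        genotype=str(meta.get("genotype", "WT")),
    )


def write_trace_csv(path: str | Path, record, kind: str) -> None:
    """Write a record as annotated CSV (inverse of :func:`read_trace_csv`)."""
    path = Path(path)
    if kind == "single_channel":
        meta = {
            "sample_rate_Hz": record.sample_rate,
            "filter_cutoff_Hz": record.filter_cutoff,
            "voltage_mV": record.voltage,
            "permeant_ion": record.permeant_ion,
            "genotype": record.genotype,
        }
        df = pd.DataFrame(
            {"time_s": record.time, "current_pA": record.samples}
        )
    elif kind == "ramp":
        meta = {"capacitance_pF": record.capacitance}
        meta.update(
            {k: v for k, v in record.condition.items() if not isinstance(v, (dict, list))}
        )
        df = pd.DataFrame(
            {
                "time_s": record.time,
                "voltage_mV": record.voltage,
                "current_pA": record.current,
            }
        )
    elif kind == "flux":
        meta = {
            k: (json.dumps(v) if isinstance(v, (dict, list)) else v)
            for k, v in record.meta.items()
        }
        df = pd.DataFrame(
            {
                "time_s": record.time,
                "F_ca_ex": record.f_ca_ex,
                "F_fura340": record.f_fura340,
                "F_fura380": record.f_fura380,
                "F_tmrm_num": record.f_tmrm_num,
                "F_tmrm_den": record.f_tmrm_den,
            }
        )
    elif kind == "imaging":
        meta = {
            "cell_id": record.cell_id,
            "dish_id": record.dish_id,
            "stimulus_time_s": record.stimulus_time,
            "genotype": record.genotype,
        }
        df = pd.DataFrame(
            {
                "time_s": record.time,
                "F340": record.f340,
                "F380": record.f380,
                "F_cepia": record.f_cepia,
            }
        )
    else:
        raise ValueError(f"unknown trace kind {kind!r}")
    with open(path, "w") as fh:
        fh.write(f"# kind={kind}\n")
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
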