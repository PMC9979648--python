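"""Reading and writing current traces, event tables and calibration tables.

The native trace format is a self-describing TSV: ``#``-prefixed
``key=value`` metadata lines (``sampling_rate_hz``, ``voltage_mv``,
``label``, optionally ``temperature_c``) followed by one current sample
(pA) per line.  Time is implicit — sample *i* occurs at ``i /
sampling_rate`` — so resampling is never needed and never supported.

Units are fixed throughout the package: currents in pA, voltages in mV,
conductances in nS (pA/mV), durations in ms, sampling rates in Hz.  With
these choices conductance is a plain division with no conversion factor.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "TraceFormatError",
    "EVENT_COLUMNS",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_calibration_table",
    "read_nmer_table",
]


class TraceFormatError(ValueError):
    """Raised when a trace file is missing metadata or contains bad rows."""


@dataclass
class CurrentTrace:
    """A uniformly sampled single-channel current recording.

    Parameters
    ----------
    samples : ndarray
        Current values in pA.
    sampling_rate : float
        Acquisition rate in Hz.  Must be positive.
    voltage : float
        Constant applied potential in mV for the whole trace.
    label : str
        Free-text recording identifier.
    temperature : float
        Recording temperature in °C (metadata only; default 22).
    """

    samples: np.ndarray
    sampling_rate: float
    voltage: float
    label: str = ""
    temperature: float = 22.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds (index / sampling_rate)."""
        return np.arange(self.samples.size) / self.sampling_rate


# Fixed column order of the event-table TSV.
EVENT_COLUMNS = [
    "trace",
    "kind",
    "start",
    "end",
    "class",
    "level_pa",
    "conductance_ns",
    "rms_pa",
    "duration_ms",
]


def _parse_header(lines: list[str], path: str) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    else:
        i = len(lines)
    required = ("sampling_rate_hz", "voltage_mv")
    for key in required:
        if key not in meta:
            raise TraceFormatError(f"{path}: header is missing '{key}'")
    return meta, i


def read_trace(path: str | os.PathLike) -> CurrentTrace:
    """Read a trace TSV written by :func:`write_trace`.

    Raises
    ------
    TraceFormatError
        If the metadata header is incomplete or a data row is not numeric
        (the error names the offending line number).
    """
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    meta, first_data = _parse_header(lines, str(path))
    values = []
    for lineno, line in enumerate(lines[first_data:], start=first_data + 1):
        if not line.strip():
            continue
        try:
            values.append(float(line))
        except ValueError as exc:
            raise TraceFormatError(
                f"{path}: non-numeric sample on line {lineno}: {line!r}"
            ) from exc
    return CurrentTrace(
        samples=np.array(values, dtype=np.float64),
        sampling_rate=float(meta["sampling_rate_hz"]),
        voltage=float(meta["voltage_mv"]),
        label=meta.get("label", ""),
        temperature=float(meta.get("temperature_c", 22.0)),
    )


def write_trace(trace: CurrentTrace, path: str | os.PathLike) -> None:
    """Write a trace in the native TSV format at full float precision."""
    buf = io.StringIO()
    buf.write(f"# sampling_rate_hz={trace.sampling_rate!r}\n")
    buf.write(f"# voltage_mv={trace.voltage!r}\n")
    buf.write(f"# label={trace.label}\n")
    buf.write(f"# temperature_c={trace.temperature!r}\n")
    for v in trace.samples:
        buf.write(f"{float(v)!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_events(events: pd.DataFrame, path: str | os.PathLike,
                 header_meta: dict | None = None) -> None:
    """Write an event table as TSV with the fixed column order.

    ``header_meta`` (e.g. a seed) is emitted as ``#`` comment lines so the
    file stays self-describing.
    """
    table = events.copy()
    for col in EVENT_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table = table[EVENT_COLUMNS]
    with open(path, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_events(path: str | os.PathLike) -> pd.DataFrame:
    """Read an event-table TSV back into a DataFrame."""
    try:
        table = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceFormatError(f"{path}: cannot parse event table: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise TraceFormatError(f"{path}: event table missing columns {missing}")
    return table[EVENT_COLUMNS]


def read_calibration_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a conductance→diameter calibration TSV.

    Columns: ``protein``, ``conductance_ns``, ``diameter_nm``.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("protein", "conductance_ns", "diameter_nm"):
        if col not in table.columns:
            raise TraceFormatError(f"{path}: calibration table missing '{col}'")
    if (table["conductance_ns"] <= 0).any() or (table["diameter_nm"] <= 0).any():
        raise TraceFormatError(f"{path}: conductances and diameters must be positive")
    return table


def read_nmer_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an n-mer → modeled-diameter TSV (columns ``n``, ``diameter_nm``)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("n", "diameter_nm"):
        if col not in table.columns:
            raise TraceFormatError(f"{path}: n-mer table missing '{col}'")
    table = table.sort_values("n").reset_index(drop=True)
    if not table["diameter_nm"].is_monotonic_increasing:
        raise TraceFormatError(f"{path}: modeled diameters must increase with n")
    return table
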