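"""Transient current-blockade (translocation) analysis.

Within an open-pore state, an analyte passing the pore transiently
reduces the current.  A blockade spans the samples deflected below
``open_level − threshold``; its duration is the deflection time from
the mean open current, its amplitude the mean open level minus the mean
blocked level, and its blocking conductance amplitude/voltage (nS).
Events at or above the translocation duration cutoff (default 3 ms) are
discarded as pore-derived noise, and events shorter than the time
resolution are dropped.

Event statistics are summarized by a Monte-Carlo bootstrap: B replicate
means of ``sample_size`` draws with replacement (defaults 30 and
65,536), from which a scatter subsample (default 300) is drawn without
replacement for plotting, all under an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace_io import CurrentTrace

__all__ = [
    "BlockadeEvent",
    "BlockadeConfig",
    "BootstrapResult",
    "detect_blockades",
    "blockade_conductance",
    "event_frequency",
    "bootstrap_means",
    "subsample_bootstrap",
    "compare_conditions",
]


@dataclass
class BlockadeEvent:
    start: int
    end: int
    duration_ms: float
    amplitude_pa: float        # mean open − mean blocked, > 0
    blocking_conductance_ns: float
    trace_label: str = ""
    voltage_mv: float = float("nan")

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("blockade duration must be positive")
        if self.amplitude_pa <= 0:
            raise ValueError("blockade amplitude must be positive "
                             "(blockades decrease the current)")


@dataclass
class BlockadeConfig:
    """Detection thresholds for blockade events.

    ``threshold_pa`` is the absolute drop below the mean open current
    that starts an event (alternatively give ``threshold_fraction`` of
    the open level).  ``max_duration_ms`` is the translocation filter:
    events lasting that long or longer are treated as pore noise and
    excluded.  ``min_duration_samples`` drops sub-resolution events.
    """

    threshold_pa: float | None = 20.0
    threshold_fraction: float | None = None
    max_duration_ms: float | None = 3.0
    min_duration_samples: int = 2
    debounce_samples: int = 0

    def resolve_threshold(self, open_level: float) -> float:
        if self.threshold_fraction is not None:
            thr = self.threshold_fraction * open_level
        elif self.threshold_pa is not None:
            thr = self.threshold_pa
        else:
            raise ValueError("set threshold_pa or threshold_fraction")
        if thr <= 0:
            raise ValueError("blockade threshold must be positive")
        return thr


@dataclass
class BootstrapResult:
    replicate_means: np.ndarray
    sample_size: int
    B: int
    seed: int

    @property
    def grand_mean(self) -> float:
        return float(np.mean(self.replicate_means))

    @property
    def replicate_sd(self) -> float:
        return float(np.std(self.replicate_means, ddof=1))


def detect_blockades(trace: CurrentTrace, open_level: float,
                     config: BlockadeConfig | None = None
                     ) -> list[BlockadeEvent]:
    """Detect blockades in an open-pore trace.

    An event spans the run of samples below ``open_level − threshold``;
    duration is the deflection time from the mean open current and
    amplitude the open mean minus the event mean.  The translocation
    duration filter and the sub-resolution cut are applied before
    returning.
    """
    config = config or BlockadeConfig()
    if open_level <= 0:
        raise ValueError("open_level must be positive")
    threshold = config.resolve_threshold(open_level)
    if open_level <= threshold:
        raise ValueError("open_level must exceed the detection threshold")
    x = trace.samples
    rate = trace.sampling_rate

    below = x < (open_level - threshold)
    open_mean = float(np.mean(x[~below])) if (~below).any() else open_level

    padded = np.concatenate(([False], below, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)

    if config.debounce_samples > 0 and starts.size > 1:
        keep_s, keep_e = [int(starts[0])], [int(ends[0])]
        for s, e in zip(starts[1:], ends[1:]):
            if s - keep_e[-1] <= config.debounce_samples:
                keep_e[-1] = int(e)
            else:
                keep_s.append(int(s))
                keep_e.append(int(e))
        starts, ends = np.array(keep_s), np.array(keep_e)

    events: list[BlockadeEvent] = []
    for s, e in zip(starts, ends):
        if e - s < config.min_duration_samples:
            continue
        duration_ms = (e - s) / rate * 1e3
        if config.max_duration_ms is not None \
                and duration_ms >= config.max_duration_ms:
            continue
        amplitude = open_mean - float(np.mean(x[s:e]))
        if amplitude <= 0:
            continue
        events.append(BlockadeEvent(
            start=int(s), end=int(e), duration_ms=duration_ms,
            amplitude_pa=amplitude,
            blocking_conductance_ns=amplitude / trace.voltage
            if trace.voltage != 0 else float("nan"),
            trace_label=trace.label, voltage_mv=trace.voltage))
    return events


def blockade_conductance(event: BlockadeEvent) -> float:
    """Blocking conductance (nS): amplitude (pA) / voltage (mV)."""
    if not np.isfinite(event.voltage_mv) or event.voltage_mv == 0:
        raise ValueError("event voltage is zero or unknown")
    return event.amplitude_pa / event.voltage_mv


def event_frequency(events_per_recording: list[list[BlockadeEvent]],
                    durations_s: list[float],
                    voltages_mv: list[float]) -> pd.DataFrame:
    """Per-voltage blockade frequency, mean ± SE over recordings.

    Each recording contributes one rate (count/duration, s⁻¹);
    recordings are grouped by voltage and summarized by the mean and the
    standard error across recordings (SE is NaN for a single recording).
    """
    if not (len(events_per_recording) == len(durations_s) == len(voltages_mv)):
        raise ValueError("events, durations and voltages must align")
    rows = []
    for events, dur, v in zip(events_per_recording, durations_s, voltages_mv):
        if dur <= 0:
            raise ValueError("recording duration must be positive")
        rows.append({"voltage_mv": v, "rate_per_s": len(events) / dur})
    per_rec = pd.DataFrame(rows)
    out = (per_rec.groupby("voltage_mv")["rate_per_s"]
           .agg(mean_rate_per_s="mean",
                se_rate_per_s=lambda r: r.std(ddof=1) / np.sqrt(len(r)),
                n_recordings="count")
           .reset_index()
           .sort_values("voltage_mv")
           .reset_index(drop=True))
    return out


def bootstrap_means(values, sample_size: int = 30, B: int = 65_536,
                    seed: int = 0) -> BootstrapResult:
    """Monte-Carlo bootstrap of the mean.

    Draws ``B`` resamples of ``sample_size`` values with replacement and
    returns the replicate means; deterministic under ``seed``.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap needs a non-empty sample")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, sample_size))
    means = values[idx].mean(axis=1)
    return BootstrapResult(replicate_means=means, sample_size=sample_size,
                           B=B, seed=seed)


def subsample_bootstrap(result: BootstrapResult, n: int = 300,
                        seed: int = 0) -> np.ndarray:
    """Draw ``n`` replicate means without replacement (scatter-plot data)."""
    if n > result.B:
        raise ValueError(f"cannot draw {n} values from {result.B} replicates")
    rng = np.random.default_rng(seed)
    idx = rng.choice(result.B, size=n, replace=False)
    return result.replicate_means[idx]


def compare_conditions(control_events: list[BlockadeEvent],
                       analyte_events: list[BlockadeEvent],
                       sample_size: int = 30, B: int = 65_536,
                       scatter_n: int = 300,
                       seed: int = 0) -> dict:
    """Bootstrap-center comparison of two blockade-event populations.

    For each condition and each dimension (blocking conductance,
    duration), runs the bootstrap and reports the grand-mean center plus
    a scatter subsample.  The conditions are explicit inputs — selecting
    which events constitute pore-derived noise vs. analyte signal is the
    caller's responsibility.
    """
    if not control_events or not analyte_events:
        raise ValueError("both conditions need at least one event")
    out: dict = {}
    for name, events, offset in (("control", control_events, 0),
                                 ("analyte", analyte_events, 1)):
        cond: dict = {}
        for j, (dim, getter) in enumerate((
                ("blocking_conductance_ns",
                 lambda e: e.blocking_conductance_ns),
                ("duration_ms", lambda e: e.duration_ms))):
            values = [getter(e) for e in events]
            boot = bootstrap_means(values, sample_size=sample_size, B=B,
                                   seed=seed + 2 * offset + j)
            cond[dim] = {
                "center": boot.grand_mean,
                "sd": boot.replicate_sd,
                "scatter": subsample_bootstrap(
                    boot, n=min(scatter_n, B), seed=seed + 10 + 2 * offset + j),
            }
        out[name] = cond
    return out
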