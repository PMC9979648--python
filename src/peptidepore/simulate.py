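"""Synthetic current-trace generator with exact ground truth.

The simulator emulates planar-bilayer recordings of pore-forming
β-hairpin peptides at the acquisition settings used throughout the
package: 20 kHz sampling with 4 kHz low-pass character, baseline at
0 pA, openings positive, blockades decreasing toward 0 pA.

Four opening archetypes are produced, mirroring the signal taxonomy the
classifier implements:

``step``
    abrupt (<10 ms) logistic rise to a single level G×V with low
    open-state noise — a stable single pore.
``square_top``
    abrupt rise followed by a staircase through ≥2 sub-levels —
    a stable pore gaining/losing monomers.
``multi``
    abrupt rise to a level whose open-state spread is far larger than
    the baseline spread — an unstable pore.
``erratic``
    slow (>10 ms) rise — membrane disruption rather than a pore.

Noise is filtered white Gaussian noise: a white series of the requested
SD is passed through a zero-phase Butterworth low-pass at the cutoff.
The clean event waveform is added after filtering so scheduled levels,
rise times and ground-truth indices are exact; the amplifier filter in a
real rig shapes noise on the sub-millisecond scale and leaves the ≥ms
event morphology essentially untouched.  Event rises are logistic ramps
whose 10–90% width equals the requested rise time, matching the
classifier's rise-time convention.

All randomness flows through one ``numpy`` Generator seeded from the
config, so a fixed seed reproduces traces bit for bit.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .trace_io import CurrentTrace, write_trace

__all__ = [
    "OpenEventSpec",
    "SimulationConfig",
    "OpenTruth",
    "BlockadeTruth",
    "GroundTruth",
    "SimulationConfigError",
    "simulate_trace",
    "simulate_blockades",
    "make_fixture_suite",
    "archetype_event",
]

ARCHETYPES = ("step", "square_top", "multi", "erratic")


class SimulationConfigError(ValueError):
    """Invalid or inconsistent simulation configuration."""


@dataclass
class OpenEventSpec:
    """One scheduled pore-opening event.

    ``conductance`` is a single nS value, or an ordered list of sub-level
    conductances for ``square_top`` (paired with ``sublevel_dwells_s``).
    ``rise_ms`` is the 10–90% rise of the logistic ramp for the abrupt
    archetypes; ``ramp_ms`` plays the same role for ``erratic`` and must
    exceed 10 ms so the archetype lands on the erratic side of the
    classifier's rise threshold.  ``open_extra_sd`` is white noise (pA,
    pre-filter) added during the open state on top of the baseline noise.
    """

    archetype: str
    conductance: float | list[float]
    duration_s: float
    rise_ms: float = 2.0
    ramp_ms: float = 50.0
    open_extra_sd: float = 0.0
    sublevel_dwells_s: list[float] | None = None
    start_s: float | None = None

    def levels(self) -> list[float]:
        if isinstance(self.conductance, (int, float)):
            return [float(self.conductance)]
        return [float(g) for g in self.conductance]

    def validate(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise SimulationConfigError(f"unknown archetype {self.archetype!r}")
        if self.duration_s <= 0:
            raise SimulationConfigError("duration_s must be positive")
        if self.open_extra_sd < 0:
            raise SimulationConfigError("open_extra_sd must be >= 0")
        levels = self.levels()
        if any(g <= 0 for g in levels):
            raise SimulationConfigError("conductances must be positive")
        if self.archetype == "square_top":
            if len(levels) < 2:
                raise SimulationConfigError("square_top needs >= 2 sub-levels")
            if (self.sublevel_dwells_s is None
                    or len(self.sublevel_dwells_s) != len(levels)):
                raise SimulationConfigError(
                    "square_top needs one dwell per sub-level")
            if abs(sum(self.sublevel_dwells_s) - self.duration_s) > 1e-9:
                raise SimulationConfigError(
                    "sub-level dwells must sum to duration_s")
        elif len(levels) != 1:
            raise SimulationConfigError(
                f"{self.archetype} takes a single conductance")
        if self.archetype == "erratic":
            if not self.ramp_ms > 10:
                raise SimulationConfigError("erratic requires ramp_ms > 10")
        else:
            if not self.rise_ms < 10:
                raise SimulationConfigError(
                    f"{self.archetype} requires rise_ms < 10")


@dataclass
class SimulationConfig:
    """Recording-level simulation parameters.

    Defaults follow the acquisition settings the analysis assumes:
    20 kHz sampling with a 4 kHz low-pass, constant applied voltage, and
    baseline current centred on 0 pA.  ``baseline_sd`` is the SD of the
    white noise before filtering (1.5 pA default, a typical quiet bilayer
    at this bandwidth).
    """

    voltage: float = 100.0
    duration_s: float = 10.0
    sampling_rate: float = 20_000.0
    lowpass_cutoff: float = 4_000.0
    baseline_sd: float = 1.5
    open_events: list[OpenEventSpec] = field(default_factory=list)
    blockade_rate_per_s: float = 0.0
    blockade_mean_depth: float = 0.45   # nS
    blockade_depth_sd: float = 0.03     # nS, event-to-event spread
    # log-normal dwell located so the MEAN dwell is 1.3 ms at the
    # default spread (mean of lognormal = exp(mu + sigma^2/2))
    blockade_logmean_duration_ms: float = float(np.log(1.3) - 0.125)
    blockade_logsd: float = 0.5
    seed: int = 0
    label: str = "sim"

    def validate(self) -> None:
        if self.sampling_rate < 2 * self.lowpass_cutoff:
            raise SimulationConfigError(
                "sampling_rate must be >= 2 x lowpass_cutoff")
        for name in ("duration_s", "sampling_rate", "lowpass_cutoff"):
            if getattr(self, name) <= 0:
                raise SimulationConfigError(f"{name} must be positive")
        for name in ("baseline_sd", "blockade_rate_per_s",
                     "blockade_mean_depth", "blockade_depth_sd",
                     "blockade_logsd"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        for spec in self.open_events:
            spec.validate()


@dataclass
class OpenTruth:
    archetype: str
    start: int
    end: int
    levels_pa: list[float]
    conductances_ns: list[float]
    rise_ms: float


@dataclass
class BlockadeTruth:
    start: int
    end: int
    duration_ms: float
    depth_ns: float


@dataclass
class GroundTruth:
    """Exact record of everything injected into a simulated trace."""

    open_events: list[OpenTruth] = field(default_factory=list)
    blockades: list[BlockadeTruth] = field(default_factory=list)


def _filtered_noise(rng: np.random.Generator, n: int, sd: float,
                    rate: float, cutoff: float) -> np.ndarray:
    white = rng.standard_normal(n) * sd
    if sd == 0:
        return white
    sos = sps.butter(4, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, white)


def _logistic_rise(n_event: int, rise_samples: float) -> np.ndarray:
    """Unit-amplitude logistic onset whose 10–90% width is ``rise_samples``."""
    # steepness such that the 10->90% crossing spans rise_samples;
    # center one rise time in, so the onset (1.2% of amplitude) sits at
    # the event's ground-truth start
    k = 2.0 * np.log(9.0) / max(rise_samples, 1e-9)
    center = rise_samples
    i = np.arange(n_event)
    return 1.0 / (1.0 + np.exp(-k * (i - center)))


def _event_waveform(spec: OpenEventSpec, voltage: float,
                    rate: float) -> np.ndarray:
    n = int(round(spec.duration_s * rate))
    levels = [g * voltage for g in spec.levels()]
    if spec.archetype == "erratic":
        rise_samples = spec.ramp_ms * 1e-3 * rate
        wave = levels[0] * _logistic_rise(n, rise_samples)
    elif spec.archetype == "square_top":
        rise_samples = spec.rise_ms * 1e-3 * rate
        wave = levels[0] * _logistic_rise(n, rise_samples)
        edges = np.cumsum([int(round(d * rate))
                           for d in spec.sublevel_dwells_s])
        for lvl, lo, hi in zip(levels[1:], edges[:-1], edges[1:]):
            wave[lo:min(hi, n)] = lvl
    else:  # step / multi
        rise_samples = spec.rise_ms * 1e-3 * rate
        wave = levels[0] * _logistic_rise(n, rise_samples)
    return wave


def simulate_trace(config: SimulationConfig) -> tuple[CurrentTrace, GroundTruth]:
    """Simulate a trace containing the scheduled opening events.

    Events without an explicit ``start_s`` are laid out sequentially with
    a 1.5 s baseline lead and 1.5 s gaps, so every event has a full
    baseline window before it.  Scheduled events that overlap or overrun
    the trace raise :class:`SimulationConfigError` — nothing is silently
    clipped.
    """
    config.validate()
    rate = config.sampling_rate
    n = int(round(config.duration_s * rate))
    rng = np.random.default_rng(config.seed)

    # resolve start times
    cursor = 1.5
    placed: list[tuple[int, int, OpenEventSpec]] = []
    for spec in config.open_events:
        start_s = spec.start_s if spec.start_s is not None else cursor
        start = int(round(start_s * rate))
        end = start + int(round(spec.duration_s * rate))
        if end > n:
            raise SimulationConfigError(
                f"event at {start_s:.3f}s overruns the trace "
                f"({end} > {n} samples); events are rejected, not clipped")
        placed.append((start, end, spec))
        cursor = max(cursor, start_s) + spec.duration_s + 1.5
    placed.sort(key=lambda t: t[0])
    for (s0, e0, _), (s1, _, _) in zip(placed, placed[1:]):
        if s1 < e0:
            raise SimulationConfigError("scheduled events overlap")

    waveform = np.zeros(n)
    extra_sd = np.zeros(n)
    truth = GroundTruth()
    for start, end, spec in placed:
        waveform[start:end] += _event_waveform(spec, config.voltage, rate)
        extra_sd[start:end] = spec.open_extra_sd
        truth.open_events.append(OpenTruth(
            archetype=spec.archetype,
            start=start,
            end=end,
            levels_pa=[g * config.voltage for g in spec.levels()],
            conductances_ns=spec.levels(),
            rise_ms=(spec.ramp_ms if spec.archetype == "erratic"
                     else spec.rise_ms),
        ))

    white = rng.standard_normal(n) * config.baseline_sd
    white += rng.standard_normal(n) * extra_sd
    sos = sps.butter(4, config.lowpass_cutoff, btype="low",
                     fs=rate, output="sos")
    noise = sps.sosfiltfilt(sos, white)

    trace = CurrentTrace(samples=waveform + noise, sampling_rate=rate,
                         voltage=config.voltage, label=config.label)
    return trace, truth


def simulate_blockades(config: SimulationConfig,
                       open_level: float) -> tuple[CurrentTrace, GroundTruth]:
    """Simulate an open-pore trace with transient current blockades.

    The trace sits at ``open_level`` (pA) with baseline-style noise.
    Blockade arrivals are homogeneous Poisson at
    ``config.blockade_rate_per_s``; each subtracts ``depth × V`` pA
    (depth drawn around ``blockade_mean_depth`` nS) for a log-normal
    dwell.  Arrivals that would overrun the trace end or overlap the
    previous blockade are dropped, never truncated; the ground truth
    lists exactly the injected events.
    """
    config.validate()
    if open_level <= 0:
        raise SimulationConfigError("open_level must be positive")
    rate = config.sampling_rate
    n = int(round(config.duration_s * rate))
    rng = np.random.default_rng(config.seed)

    waveform = np.full(n, float(open_level))
    truth = GroundTruth()
    if config.blockade_rate_per_s > 0:
        t = 0.0
        last_end = -1
        while True:
            t += rng.exponential(1.0 / config.blockade_rate_per_s)
            if t >= config.duration_s:
                break
            dur_ms = float(rng.lognormal(config.blockade_logmean_duration_ms,
                                         config.blockade_logsd))
            depth_ns = float(rng.normal(config.blockade_mean_depth,
                                        config.blockade_depth_sd))
            depth_ns = max(depth_ns, 0.05 * config.blockade_mean_depth)
            start = int(round(t * rate))
            end = start + max(int(round(dur_ms * 1e-3 * rate)), 1)
            if end > n or start <= last_end:
                continue  # rejected, not clipped
            waveform[start:end] -= depth_ns * abs(config.voltage)
            truth.blockades.append(BlockadeTruth(
                start=start, end=end,
                duration_ms=(end - start) / rate * 1e3,
                depth_ns=depth_ns))
            last_end = end

    noise = _filtered_noise(rng, n, config.baseline_sd, rate,
                            config.lowpass_cutoff)
    trace = CurrentTrace(samples=waveform + noise, sampling_rate=rate,
                         voltage=config.voltage, label=config.label)
    return trace, truth


def archetype_event(archetype: str, conductance: float = 1.1,
                    duration_s: float = 2.0, rise_ms: float = 2.0,
                    baseline_sd: float = 1.5) -> OpenEventSpec:
    """A canonical :class:`OpenEventSpec` for one archetype.

    Open-state extra noise is chosen so each archetype lands squarely in
    its class: quiet for step/square_top, ~15× the baseline spread for
    multi (the taxonomy's instability criterion is 10×), moderate for
    erratic whose class is decided by its slow rise alone.  ``multi`` and
    ``erratic`` events are kept under 1 s — unstable pores and membrane
    disruptions are transient — which also keeps them clear of the
    1 s long-event step rule.
    """
    if archetype == "step":
        # open-state noise grows mildly with conductance, mirroring the
        # conductance dependence the RMS normalization corrects for
        return OpenEventSpec("step", conductance, duration_s,
                             rise_ms=rise_ms,
                             open_extra_sd=0.5 + 2.0 * conductance)
    if archetype == "square_top":
        k = 3
        dwell = duration_s / k
        return OpenEventSpec(
            "square_top",
            [conductance * (1 + 0.5 * j) for j in range(k)],
            duration_s, rise_ms=rise_ms,
            open_extra_sd=0.5,
            sublevel_dwells_s=[dwell] * k)
    if archetype == "multi":
        return OpenEventSpec("multi", conductance,
                             min(duration_s, 0.8), rise_ms=rise_ms,
                             open_extra_sd=15.0 * baseline_sd)
    if archetype == "erratic":
        return OpenEventSpec("erratic", conductance,
                             min(duration_s, 0.8), ramp_ms=60.0,
                             open_extra_sd=1.0)
    raise SimulationConfigError(f"unknown archetype {archetype!r}")


def _truth_rows(truth: GroundTruth) -> list[str]:
    rows = ["kind\tarchetype\tstart\tend\tlevels_pa\tconductances_ns\tduration_ms\tdepth_ns"]
    for ev in truth.open_events:
        rows.append("open\t%s\t%d\t%d\t%s\t%s\t\t" % (
            ev.archetype, ev.start, ev.end,
            ",".join(repr(v) for v in ev.levels_pa),
            ",".join(repr(v) for v in ev.conductances_ns)))
    for b in truth.blockades:
        rows.append("blockade\t\t%d\t%d\t\t\t%r\t%r" % (
            b.start, b.end, b.duration_ms, b.depth_ns))
    return rows


def write_ground_truth(truth: GroundTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_truth_rows(truth)) + "\n")


def make_fixture_suite(out_dir: str | os.PathLike, seed: int = 0,
                       events_per_archetype: int = 5) -> "pd.DataFrame":
    """Write the standard labelled fixture suite and return its manifest.

    One trace per opening archetype (``events_per_archetype`` events
    each), one mixed trace containing all four archetypes, and one
    blockade trace at each of +50/+100/+150/+200 mV with the blockade
    arrival rate doubling per 50 mV step — the qualitative
    voltage-dependence the blockade analysis is designed to read out.
    Ground truth is written next to every trace; the manifest records
    files, seeds and content hashes.
    """
    import pandas as pd

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest_rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) % (2 ** 31) for s in
                   ss.generate_state(5 + 4, dtype=np.uint64)]

    # step conductances cycle through the characteristic peak values so
    # downstream histogram and RMS-vs-G fits see a spread of pore sizes
    per_archetype_g = {"step": (1.1, 0.8, 0.4), "square_top": (0.8,),
                      "multi": (0.8,), "erratic": (0.8,)}
    for idx, archetype in enumerate(ARCHETYPES):
        gs = per_archetype_g[archetype]
        events = [archetype_event(archetype, conductance=gs[i % len(gs)])
                  for i in range(events_per_archetype)]
        total = 1.5 + sum(e.duration_s + 1.5 for e in events) + 1.0
        cfg = SimulationConfig(voltage=100.0, duration_s=total,
                               open_events=events,
                               seed=child_seeds[idx],
                               label=f"fixture_{archetype}")
        trace, truth = simulate_trace(cfg)
        _emit(out_dir, f"{archetype}", trace, truth, cfg.seed, manifest_rows)

    mixed_events = [archetype_event(a) for a in ARCHETYPES]
    total = 1.5 + sum(e.duration_s + 1.5 for e in mixed_events) + 1.0
    cfg = SimulationConfig(voltage=100.0, duration_s=total,
                           open_events=mixed_events, seed=child_seeds[4],
                           label="fixture_mixed")
    trace, truth = simulate_trace(cfg)
    _emit(out_dir, "mixed", trace, truth, cfg.seed, manifest_rows)

    base_rate = 0.5
    for j, voltage in enumerate((50.0, 100.0, 150.0, 200.0)):
        cfg = SimulationConfig(
            voltage=voltage, duration_s=30.0,
            blockade_rate_per_s=base_rate * 2 ** j,
            seed=child_seeds[5 + j],
            label=f"fixture_blockade_{int(voltage)}mV")
        trace, truth = simulate_blockades(cfg, open_level=2.0 * voltage)
        _emit(out_dir, f"blockade_{int(voltage)}mV", trace, truth,
              cfg.seed, manifest_rows)

    manifest = pd.DataFrame(manifest_rows,
                            columns=["name", "trace_file", "truth_file",
                                     "seed", "sha256"])
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"),
                    sep="\t", index=False)
    return manifest


def _emit(out_dir: str, name: str, trace: CurrentTrace, truth: GroundTruth,
          seed: int, manifest_rows: list) -> None:
    trace_file = os.path.join(out_dir, f"{name}.tsv")
    truth_file = os.path.join(out_dir, f"{name}_truth.tsv")
    write_trace(trace, trace_file)
    write_ground_truth(truth, truth_file)
    with open(trace_file, "rb") as fh:
        digest = hashlib.sha256(fh.read()).hexdigest()
    manifest_rows.append([name, os.path.basename(trace_file),
                          os.path.basename(truth_file), seed, digest])
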