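"""End-to-end orchestration: simulate → classify → characterize → blockade.

A run is driven by one :class:`RunConfig`.  Every source of randomness
derives from the single root seed through ``numpy.SeedSequence``, each
stage's outputs are plain TSV with the seed recorded in the header, and
re-running with the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import blockade as bl
from . import characterize as ch
from . import classify as cl
from . import simulate as sim
from . import trace_io

__all__ = ["RunConfig", "run_pipeline", "validate_config", "load_run_config"]

log = logging.getLogger("peptidepore")

_DATA = os.path.join(os.path.dirname(__file__), "data")


@dataclass
class RunConfig:
    out_dir: str = "peptidepore_run"
    seed: int = 0
    simulate_fixtures: bool = True
    simulate_only: bool = False
    opening_traces: list[str] = field(default_factory=list)
    blockade_traces: list[str] = field(default_factory=list)
    calibration_path: str = os.path.join(_DATA, "calibration_synthetic.tsv")
    nmer_path: str = os.path.join(_DATA, "nmer_diameters.tsv")
    classifier: cl.ClassifierConfig = field(default_factory=cl.ClassifierConfig)
    # fractional threshold adapts across voltages (the open level scales
    # with V while an absolute pA threshold does not); the 2-sample
    # debounce suppresses re-entry chatter on marginal events
    blockade_config: bl.BlockadeConfig = field(
        default_factory=lambda: bl.BlockadeConfig(
            threshold_pa=None, threshold_fraction=0.10,
            debounce_samples=2))
    bootstrap_sample_size: int = 30
    bootstrap_B: int = 65_536
    bootstrap_scatter_n: int = 300
    rms_low_noise_threshold: float = 4.0


def _stage_seeds(root: int, k: int) -> list[int]:
    state = np.random.SeedSequence(root).generate_state(k, dtype=np.uint64)
    return [int(s) % (2 ** 31) for s in state]


def validate_config(config: RunConfig) -> list[str]:
    """Return every problem with a config, without side effects."""
    problems: list[str] = []
    for name in ("calibration_path", "nmer_path"):
        path = getattr(config, name)
        if not os.path.exists(path):
            problems.append(f"{name}: no such file: {path}")
    for path in list(config.opening_traces) + list(config.blockade_traces):
        if not os.path.exists(path):
            problems.append(f"trace file missing: {path}")
    try:
        config.classifier.validate()
    except ValueError as exc:
        problems.append(f"classifier: {exc}")
    try:
        config.blockade_config.resolve_threshold(1e9)
    except ValueError as exc:
        problems.append(f"blockade_config: {exc}")
    if config.bootstrap_scatter_n > config.bootstrap_B:
        problems.append("bootstrap_scatter_n exceeds bootstrap_B")
    if config.seed < 0:
        problems.append("seed must be non-negative")
    return problems


def _classify_traces(paths: list[str], config: RunConfig) -> pd.DataFrame:
    rows = []
    for path in paths:
        trace = trace_io.read_trace(path)
        for start, end in cl.detect_openings(trace, config.classifier):
            try:
                ev = cl.analyze_opening(trace, (start, end), config.classifier)
            except ValueError as exc:
                log.warning("skipping event in %s: %s", trace.label, exc)
                continue
            g = ch.open_conductance(trace, ev)
            rms = ch.rms_noise(trace, ev)
            rows.append({
                "trace": trace.label or os.path.basename(path),
                "kind": "open", "start": start, "end": end,
                "class": ev.label,
                "level_pa": ev.open_levels_pa[0] if ev.open_levels_pa
                else np.nan,
                "conductance_ns": g, "rms_pa": rms,
                "duration_ms": ev.duration_s * 1e3,
                "voltage_mv": trace.voltage,
            })
    return pd.DataFrame(rows)


def _analyze_blockades(paths: list[str], config: RunConfig,
                       seeds: list[int]) -> tuple[pd.DataFrame, pd.DataFrame,
                                                  pd.DataFrame]:
    all_events, per_rec, durations, voltages = [], [], [], []
    for path in paths:
        trace = trace_io.read_trace(path)
        open_level = float(np.median(trace.samples))
        events = bl.detect_blockades(trace, open_level,
                                     config.blockade_config)
        per_rec.append(events)
        durations.append(trace.duration_s)
        voltages.append(trace.voltage)
        all_events.extend(events)
    event_rows = [{
        "trace": e.trace_label, "kind": "blockade", "start": e.start,
        "end": e.end, "class": "", "level_pa": -e.amplitude_pa,
        "conductance_ns": e.blocking_conductance_ns, "rms_pa": np.nan,
        "duration_ms": e.duration_ms, "voltage_mv": e.voltage_mv,
    } for e in all_events]
    freq = bl.event_frequency(per_rec, durations, voltages) \
        if per_rec else pd.DataFrame()

    boot_rows = []
    for j, (events, v) in enumerate(zip(per_rec, voltages)):
        if len(events) < 2:
            continue
        for dim, getter in (("blocking_conductance_ns",
                             lambda e: e.blocking_conductance_ns),
                            ("duration_ms", lambda e: e.duration_ms)):
            boot = bl.bootstrap_means(
                [getter(e) for e in events],
                sample_size=config.bootstrap_sample_size,
                B=config.bootstrap_B, seed=seeds[j])
            boot_rows.append({
                "voltage_mv": v, "dimension": dim, "n_events": len(events),
                "center": boot.grand_mean, "replicate_sd": boot.replicate_sd,
                "sample_size": boot.sample_size, "B": boot.B,
                "seed": boot.seed,
            })
    return pd.DataFrame(event_rows), freq, pd.DataFrame(boot_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write all outputs under ``out_dir``.

    Returns the machine-readable report (also written as
    ``report.tsv``).  A stage failure aborts with the stage name in the
    exception message.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = _stage_seeds(config.seed, 16)
    report: dict = {"seed": config.seed}

    opening_traces = list(config.opening_traces)
    blockade_traces = list(config.blockade_traces)

    if config.simulate_fixtures:
        fixture_dir = os.path.join(config.out_dir, "traces")
        manifest = sim.make_fixture_suite(fixture_dir, seed=seeds[0])
        report["n_fixture_traces"] = int(len(manifest))
        for row in manifest.itertuples():
            path = os.path.join(fixture_dir, row.trace_file)
            if row.name.startswith("blockade"):
                blockade_traces.append(path)
            else:
                opening_traces.append(path)
    if config.simulate_only:
        _write_report(report, config)
        return report

    header = {"seed": config.seed}

    # --- classification ---
    events = _classify_traces(opening_traces, config)
    trace_io.write_events(events, os.path.join(config.out_dir, "events.tsv"),
                          header_meta=header)
    report["n_open_events"] = int(len(events))
    if len(events):
        ratios = events["class"].value_counts(normalize=True)
        ratio_table = pd.DataFrame({
            "class": cl.SIGNAL_CLASSES,
            "fraction": [float(ratios.get(c, 0.0))
                         for c in cl.SIGNAL_CLASSES]})
        _write_tsv(ratio_table, os.path.join(config.out_dir,
                                             "class_ratios.tsv"), header)
        for c in cl.SIGNAL_CLASSES:
            report[f"ratio_{c}"] = float(ratios.get(c, 0.0))

    # --- pore characterization (step events only, per definition) ---
    steps = events[events["class"] == "step"] if len(events) else events
    if len(steps) >= 1:
        cal = ch.calibration_from_table(
            trace_io.read_calibration_table(config.calibration_path))
        nmer = trace_io.read_nmer_table(config.nmer_path)
        char_rows = []
        for r in steps.itertuples():
            d, extrapolated = ch.estimate_diameter(r.conductance_ns, cal)
            char_rows.append({
                "trace": r.trace, "conductance_ns": r.conductance_ns,
                "diameter_nm": d, "extrapolated": extrapolated,
                "n_mer": ch.assign_oligomer(d, nmer), "rms_pa": r.rms_pa,
            })
        char = pd.DataFrame(char_rows)
        if len(char) >= 5:
            report["conductance_peaks_ns"] = ",".join(
                "%.4g" % p
                for p in ch.conductance_peaks(char["conductance_ns"]))
        records = [ch.NoiseRecord(conductance=r.conductance_ns, rms=r.rms_pa)
                   for r in char.itertuples()]
        if sum(rec.defined for rec in records) >= 2 and \
                len({rec.conductance for rec in records if rec.defined}) >= 2:
            records, (a, b) = ch.normalize_rms(records)
            char["normalized_rms_pa"] = [rec.normalized_rms
                                         for rec in records]
            report["rms_fit_slope"] = a
            report["rms_fit_intercept"] = b
            report["low_noise_fraction"] = ch.low_noise_fraction(
                records, config.rms_low_noise_threshold)
        _write_tsv(char, os.path.join(config.out_dir, "characterize.tsv"),
                   header)
        report["median_step_conductance_ns"] = float(
            np.median(char["conductance_ns"]))
        report["modal_n_mer"] = int(char["n_mer"].mode().iloc[0])

    # --- blockade analysis ---
    if blockade_traces:
        bl_events, freq, boots = _analyze_blockades(
            blockade_traces, config, seeds[1:])
        trace_io.write_events(
            bl_events, os.path.join(config.out_dir, "blockade_events.tsv"),
            header_meta=header)
        report["n_blockade_events"] = int(len(bl_events))
        if len(freq):
            _write_tsv(freq, os.path.join(config.out_dir,
                                          "blockade_frequency.tsv"), header)
            for r in freq.itertuples():
                report[f"blockade_rate_{int(r.voltage_mv)}mV_per_s"] = \
                    float(r.mean_rate_per_s)
        if len(boots):
            _write_tsv(boots, os.path.join(config.out_dir,
                                           "bootstrap_summary.tsv"), header)

    _write_report(report, config)
    return report


def _write_tsv(frame: pd.DataFrame, path: str, header: dict) -> None:
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _write_report(report: dict, config: RunConfig) -> None:
    rows = pd.DataFrame({"key": list(report),
                         "value": [report[k] for k in report]})
    _write_tsv(rows, os.path.join(config.out_dir, "report.tsv"),
               {"seed": config.seed})
    with open(os.path.join(config.out_dir, "summary.txt"), "w") as fh:
        fh.write("peptidepore pipeline summary\n")
        for key in report:
            fh.write(f"{key}: {report[key]}\n")


def load_run_config(path: str | os.PathLike) -> RunConfig:
    """Parse a sectioned key=value config file into a :class:`RunConfig`.

    Sections ``[run]``, ``[classifier]`` and ``[blockade]`` map onto
    :class:`RunConfig`, :class:`ClassifierConfig` and
    :class:`BlockadeConfig` fields; unknown keys are an error.
    """
    sections: dict[str, dict[str, str]] = {"run": {}}
    current = "run"
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip()
                sections.setdefault(current, {})
                continue
            key, _, value = line.partition("=")
            sections[current][key.strip()] = value.strip()

    config = RunConfig()

    def apply(obj, values: dict[str, str], section: str) -> None:
        for key, raw_value in values.items():
            if not hasattr(obj, key):
                raise ValueError(f"unknown key '{key}' in [{section}]")
            current_value = getattr(obj, key)
            if isinstance(current_value, bool):
                setattr(obj, key, raw_value.lower() in ("1", "true", "yes"))
            elif isinstance(current_value, int):
                setattr(obj, key, int(raw_value))
            elif isinstance(current_value, float) or current_value is None:
                setattr(obj, key, float(raw_value))
            elif isinstance(current_value, list):
                setattr(obj, key,
                        [v for v in raw_value.split(",") if v])
            else:
                setattr(obj, key, raw_value)

    apply(config, sections.get("run", {}), "run")
    apply(config.classifier, sections.get("classifier", {}), "classifier")
    apply(config.blockade_config, sections.get("blockade", {}), "blockade")
    return config
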