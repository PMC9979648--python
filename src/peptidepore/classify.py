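"""Detection and four-class labelling of pore-opening events.

A detected opening is labelled with one of four signal classes:

``step``
    sharp rise in under 10 ms, a single open level whose 95% spread is
    under 10× the baseline spread — stable single pore.
``square_top``
    sharp rise plus a staircase of ≥2 sub-levels, each with low spread —
    stable pore with monomer insertion/dissociation.
``multi``
    sharp rise but open-state 95% spread above 10× baseline — unstable
    pore.
``erratic``
    blunt rise, slower than 10 ms — membrane disruption, not a pore.

The "95% confidence interval of the pore current value" is read as the
central 95% percentile interval of the current *samples* in the window
(97.5th − 2.5th percentile), i.e. a distribution width.  A CI of the
mean would shrink as 1/√n and make the 10× rule pass trivially on long
events; only the width reading yields a noise-sensitivity criterion.

A single-level signal lasting longer than 1 s is classed as step
(``long_event_forces_step``); that check runs after the rise-time test
and before the spread test, so a slow erratic rise is never promoted.

Sub-levels are found by penalized binary segmentation of the open-state
current into piecewise-constant means: the segment split with the
largest residual-sum-of-squares gain is accepted while the gain exceeds
``penalty × σ̂² × log n`` (σ̂ from the median absolute first difference),
then adjacent segments closer than ``staircase_min_step_pa`` are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace_io import CurrentTrace

__all__ = [
    "SignalClass",
    "ClassifierConfig",
    "OpenEvent",
    "detect_openings",
    "measure_rise_time",
    "ci_width",
    "classify_event",
    "analyze_opening",
    "select_events",
    "class_ratios",
    "segment_levels",
]

SignalClass = str  # one of SIGNAL_CLASSES
SIGNAL_CLASSES = ("step", "square_top", "multi", "erratic")


@dataclass
class ClassifierConfig:
    """Thresholds of the signal taxonomy and the detector.

    The taxonomy thresholds (10 ms rise, 10× spread ratio, 1 s step
    rule) are the classification rules themselves; the detector settings
    (``detection_k``, ``debounce_ms``, ``min_run_ms``) and the staircase
    segmentation settings are implementation knobs with conservative
    defaults.
    """

    rise_threshold_ms: float = 10.0
    ci_ratio_threshold: float = 10.0
    step_duration_s: float = 1.0
    min_event_duration_s: float = 0.0
    baseline_window_s: float = 1.0
    detection_k: float = 5.0
    detection_end_k: float = 2.5
    debounce_ms: float = 5.0
    min_run_ms: float = 1.0
    staircase_min_step_pa: float = 10.0
    staircase_penalty: float = 5.0
    staircase_min_dwell_s: float = 0.05
    long_event_forces_step: bool = True

    def validate(self) -> None:
        for name in ("rise_threshold_ms", "ci_ratio_threshold",
                     "step_duration_s", "baseline_window_s", "detection_k",
                     "debounce_ms", "staircase_min_step_pa",
                     "staircase_penalty", "staircase_min_dwell_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ClassifierConfig.{name} must be positive")
        if self.min_event_duration_s < 0:
            raise ValueError("min_event_duration_s must be >= 0")


@dataclass
class OpenEvent:
    """A detected and characterized pore-opening episode."""

    start: int
    end: int
    rise_time_ms: float = float("nan")
    open_levels_pa: list[float] = field(default_factory=list)
    ci_open_pa: list[float] = field(default_factory=list)
    ci_baseline_pa: float = float("nan")
    duration_s: float = float("nan")
    baseline_mean_pa: float = float("nan")
    label: SignalClass | None = None

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def ci_width(samples: np.ndarray) -> float:
    """Width of the central 95% interval of a sample window (pA).

    Computed as the 97.5th minus the 2.5th percentile with linear
    interpolation; for a large Gaussian window of SD σ this approaches
    2×1.96σ.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("ci_width needs at least 2 samples")
    hi, lo = np.percentile(samples, [97.5, 2.5])
    return float(hi - lo)


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return float(1.4826 * mad)


def detect_openings(trace: CurrentTrace,
                    config: ClassifierConfig | None = None
                    ) -> list[tuple[int, int]]:
    """Find pore-opening episodes as (start, end) index pairs.

    The baseline is estimated robustly (median + 1.4826·MAD).  Detection
    uses hysteresis: an event starts when the current exceeds
    ``median + detection_k × SD`` and ends when it stays below
    ``median + detection_end_k × SD`` for at least the debounce
    interval, so a slowly rising signal that chatters around the upper
    threshold is kept as one event.  Runs shorter than ``min_run_ms``
    are discarded as noise excursions.  A constant trace yields an
    empty list.
    """
    config = config or ClassifierConfig()
    config.validate()
    x = trace.samples
    rate = trace.sampling_rate
    base_n = int(round(config.baseline_window_s * rate))
    if x.size <= base_n:
        raise ValueError("trace shorter than the baseline window")

    # iterative robust baseline: clipping above median + 3 SD and
    # re-estimating converges onto the baseline level even when open
    # states occupy a large fraction of the trace
    sub = x
    med = float(np.median(sub))
    sd = _robust_sd(sub)
    for _ in range(3):
        if sd == 0:
            break
        mask = sub < med + 3.0 * sd
        if not mask.any():
            break
        sub = sub[mask]
        med = float(np.median(sub))
        sd = _robust_sd(sub)
    if sd == 0:
        return []
    thr_hi = med + config.detection_k * sd
    thr_lo = med + config.detection_end_k * sd

    above_hi = x > thr_hi
    if not above_hi.any():
        return []
    above_lo = x > thr_lo

    # runs of the low threshold, with sub-debounce gaps merged
    padded = np.concatenate(([False], above_lo, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive
    debounce = max(int(round(config.debounce_ms * 1e-3 * rate)), 1)
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < debounce:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    min_run = max(int(round(config.min_run_ms * 1e-3 * rate)), 2)
    min_dur = int(round(config.min_event_duration_s * rate))
    events: list[tuple[int, int]] = []
    for s, e in merged:
        hi = np.flatnonzero(above_hi[s:e])
        if hi.size == 0:
            continue  # never crossed the detection threshold
        # clamp both edges to detection-threshold crossings so baseline
        # noise excursions merged at the low threshold cannot pad the
        # event with near-baseline samples
        start = s + int(hi[0])
        end = s + int(hi[-1]) + 1
        if (end - start) >= max(min_run, min_dur):
            events.append((start, end))
    return events


def measure_rise_time(trace: CurrentTrace, event: tuple[int, int],
                      baseline_mean: float | None = None,
                      amplitude: float | None = None) -> float:
    """10–90% rise time of an opening, in ms.

    The crossing times are the first sample indices at or above 10% and
    90% of the first-sub-level amplitude over baseline; the rise is the
    inclusive span between them, so a one-sample jump reads as one
    sample period (0.05 ms at 20 kHz).
    """
    start, end = event
    if end - start < 3:
        raise ValueError("event needs at least 3 samples")
    x = trace.samples
    rate = trace.sampling_rate
    if baseline_mean is None:
        lo = max(0, start - int(round(rate)))
        baseline_mean = float(np.mean(x[lo:start])) if start > lo else 0.0
    seg = x[start:end]
    if amplitude is None:
        # first-sub-level estimate: median over an early post-rise window,
        # past the rise of abrupt events but before later sub-levels
        n = seg.size
        w0 = min(int(round(0.05 * rate)), n // 4)
        w1 = max(w0 + 2, min(int(round(0.25 * rate)), n // 2))
        amplitude = float(np.median(seg[w0:w1])) - baseline_mean
    if amplitude <= 0:
        return 0.0
    t10 = baseline_mean + 0.1 * amplitude
    t90 = baseline_mean + 0.9 * amplitude
    above10 = np.flatnonzero(seg >= t10)
    above90 = np.flatnonzero(seg >= t90)
    if above10.size == 0 or above90.size == 0:
        return float("nan")
    i10, i90 = int(above10[0]), int(above90[0])
    return (max(i90 - i10, 0) + 1) / rate * 1e3


def segment_levels(samples: np.ndarray, rate: float,
                   config: ClassifierConfig) -> list[tuple[int, int]]:
    """Piecewise-constant segmentation of an open-state window.

    Penalized binary segmentation: recursively accept the split with the
    largest SSE reduction while the gain exceeds
    ``staircase_penalty × σ̂² × log n``; enforce a minimum dwell; then
    merge neighbours whose means differ by < ``staircase_min_step_pa``.
    Returns (start, end) pairs relative to the window.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 4:
        return [(0, n)]
    diffs = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0)
    sigma = max(sigma, 1e-12)
    penalty = config.staircase_penalty * sigma ** 2 * np.log(n)
    min_dwell = max(int(round(config.staircase_min_dwell_s * rate)), 2)

    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(a: int, b: int) -> float:
        s, s2 = csum[b] - csum[a], csum2[b] - csum2[a]
        return s2 - s * s / (b - a)

    def best_split(a: int, b: int) -> tuple[float, int]:
        if b - a < 2 * min_dwell:
            return 0.0, -1
        ks = np.arange(a + min_dwell, b - min_dwell + 1)
        if ks.size == 0:
            return 0.0, -1
        left_s = csum[ks] - csum[a]
        left_s2 = csum2[ks] - csum2[a]
        right_s = csum[b] - csum[ks]
        right_s2 = csum2[b] - csum2[ks]
        sse_split = (left_s2 - left_s ** 2 / (ks - a)
                     + right_s2 - right_s ** 2 / (b - ks))
        j = int(np.argmin(sse_split))
        gain = sse(a, b) - float(sse_split[j])
        return gain, int(ks[j])

    segments = [(0, n)]
    changed = True
    while changed:
        changed = False
        new_segments: list[tuple[int, int]] = []
        for a, b in segments:
            gain, k = best_split(a, b)
            if k >= 0 and gain > penalty:
                new_segments.extend([(a, k), (k, b)])
                changed = True
            else:
                new_segments.append((a, b))
        segments = sorted(new_segments)

    # merge adjacent segments with indistinct means
    merged = [list(segments[0])]
    for a, b in segments[1:]:
        prev = merged[-1]
        if abs(np.mean(x[a:b]) - np.mean(x[prev[0]:prev[1]])) \
                < config.staircase_min_step_pa:
            prev[1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def analyze_opening(trace: CurrentTrace, event: tuple[int, int],
                    config: ClassifierConfig | None = None) -> OpenEvent:
    """Measure and label one detected opening.

    Requires a full baseline window immediately before the event; the
    spread statistics, rise time and sub-level structure are measured
    here and the class label assigned per the four-class rules.
    """
    config = config or ClassifierConfig()
    config.validate()
    start, end = event
    x = trace.samples
    rate = trace.sampling_rate
    base_n = int(round(config.baseline_window_s * rate))
    if start < base_n:
        raise ValueError(
            f"event at sample {start} lacks the required "
            f"{config.baseline_window_s} s pre-event baseline window "
            f"({base_n} samples)")
    baseline = x[start - base_n:start]
    baseline_mean = float(np.mean(baseline))
    ci_base = ci_width(baseline)

    rise_ms = measure_rise_time(trace, event, baseline_mean=baseline_mean)
    duration_s = (end - start) / rate

    ev = OpenEvent(start=start, end=end, rise_time_ms=rise_ms,
                   ci_baseline_pa=ci_base, duration_s=duration_s,
                   baseline_mean_pa=baseline_mean)

    # open-state region: skip the rise (3x measured rise, capped)
    skip = min(int(round(3 * rise_ms * 1e-3 * rate)), (end - start) // 2)
    open_seg = x[start + skip:end]
    if open_seg.size < 4:
        open_seg = x[start:end]

    segs = segment_levels(open_seg, rate, config)
    ev.open_levels_pa = [float(np.mean(open_seg[a:b]) - baseline_mean)
                         for a, b in segs]
    ev.ci_open_pa = [ci_width(open_seg[a:b]) if b - a >= 2 else 0.0
                     for a, b in segs]

    # --- classification rules ---
    if rise_ms > config.rise_threshold_ms:
        ev.label = "erratic"
        return ev
    single_level = len(segs) == 1
    if (config.long_event_forces_step and single_level
            and duration_s > config.step_duration_s):
        ev.label = "step"
        return ev
    ci_ratio_high = any(c > config.ci_ratio_threshold * ci_base
                        for c in ev.ci_open_pa)
    if ci_ratio_high:
        ev.label = "multi"
        return ev
    ev.label = "square_top" if len(segs) >= 2 else "step"
    return ev


def classify_event(trace: CurrentTrace, event: tuple[int, int],
                   config: ClassifierConfig | None = None) -> SignalClass:
    """Class label of one detected opening (see :func:`analyze_opening`)."""
    return analyze_opening(trace, event, config).label


def select_events(events_by_measurement: dict[str, list[OpenEvent]],
                  per_measurement: int = 20,
                  pooled: int = 50) -> list[OpenEvent]:
    """Duration-ranked event selection across measurements.

    Keeps the ``per_measurement`` longest events of each measurement
    (all if fewer), pools them, and keeps the ``pooled`` longest overall.
    Ties in duration are broken by earlier start index, then by
    measurement key, so the selection is deterministic.
    """
    def order(ev: OpenEvent):
        return (-ev.duration_s, ev.start)

    pool: list[tuple[str, OpenEvent]] = []
    for key in sorted(events_by_measurement):
        events = sorted(events_by_measurement[key], key=order)
        pool.extend((key, ev) for ev in events[:per_measurement])
    pool.sort(key=lambda t: (-t[1].duration_s, t[1].start, t[0]))
    return [ev for _, ev in pool[:pooled]]


def class_ratios(events: list[OpenEvent]) -> dict[SignalClass, float]:
    """Fraction of events per signal class; fractions sum to 1."""
    if not events:
        raise ValueError("class_ratios needs at least one event")
    counts = {c: 0 for c in SIGNAL_CLASSES}
    for ev in events:
        if ev.label not in counts:
            raise ValueError(f"event with unknown label {ev.label!r}")
        counts[ev.label] += 1
    n = len(events)
    return {c: counts[c] / n for c in SIGNAL_CLASSES}
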