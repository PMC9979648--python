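"""Open-pore conductance, pore-size calibration and RMS noise.

Conductance is the baseline-subtracted mean open current over the first
second after opening divided by the applied voltage (pA/mV = nS).  Pore
diameter comes from an empirical linear calibration against natural
β-barrel proteins of known conductance and crystallographic diameter —
an alternative to Hille's geometric equation — and oligomer number from
a nearest-diameter lookup in a modeled n-mer table.

RMS noise of the open state is defined against the pre-opening baseline:
``sqrt(var_open − var_base)`` with unbiased variances over ~1 s windows.
Because this quantity grows with conductance, records are normalized by
a linear RMS-vs-conductance fit, rescaling each record to its expected
value at a 1 nS pore; pores with normalized RMS below 4 are counted as
low-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .classify import OpenEvent
from .trace_io import CurrentTrace

__all__ = [
    "CalibrationEntry",
    "CalibrationModel",
    "NoiseRecord",
    "open_conductance",
    "conductance_peaks",
    "fit_calibration",
    "estimate_diameter",
    "assign_oligomer",
    "rms_noise",
    "normalize_rms",
    "low_noise_fraction",
]


@dataclass
class CalibrationEntry:
    protein: str
    conductance: float  # nS
    diameter: float     # nm

    def __post_init__(self) -> None:
        if self.conductance <= 0 or self.diameter <= 0:
            raise ValueError("conductance and diameter must be positive")


@dataclass
class CalibrationModel:
    """Least-squares line diameter(nm) = slope × G(nS) + intercept."""

    slope: float
    intercept: float
    residual_ss: float
    entries: list[CalibrationEntry] = field(default_factory=list)

    @property
    def g_range(self) -> tuple[float, float]:
        gs = [e.conductance for e in self.entries]
        return (min(gs), max(gs))


@dataclass
class NoiseRecord:
    conductance: float            # nS
    rms: float                    # pA; NaN when undefined
    normalized_rms: float = float("nan")
    excluded: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rms)


def open_conductance(trace: CurrentTrace, event: OpenEvent | tuple[int, int],
                     window_s: float = 1.0) -> float:
    """Open-pore conductance (nS) of a step-type opening.

    Mean current over the first ``window_s`` after the pore has opened
    (the full event if shorter), minus the pre-event baseline mean,
    divided by the applied voltage.  When the event carries a measured
    rise time the averaging window starts once the opening transition is
    complete (three rise times in), so the partially risen samples do
    not drag the level down.
    """
    if trace.voltage == 0:
        raise ValueError("applied voltage is zero; conductance undefined")
    skip = 0
    if isinstance(event, OpenEvent):
        start, end = event.start, event.end
        baseline_mean = event.baseline_mean_pa
        if not np.isfinite(baseline_mean):
            baseline_mean = None
        if np.isfinite(event.rise_time_ms):
            skip = int(round(3 * event.rise_time_ms * 1e-3
                             * trace.sampling_rate))
            skip = min(skip, (end - start) // 2)
    else:
        start, end = event
        baseline_mean = None
    rate = trace.sampling_rate
    if baseline_mean is None:
        lo = max(0, start - int(round(window_s * rate)))
        baseline_mean = float(np.mean(trace.samples[lo:start])) \
            if start > lo else 0.0
    lo = start + skip
    stop = min(end, lo + int(round(window_s * rate)))
    level = float(np.mean(trace.samples[lo:stop])) - baseline_mean
    return level / trace.voltage


def conductance_peaks(conductances, bin_width: float = 0.05,
                      method: str = "kde") -> list[float]:
    """Peak locations (nS) of a conductance distribution, ascending.

    ``kde`` (default) uses a Gaussian kernel-density estimate with
    Silverman bandwidth and reports local maxima; ``hist`` reports the
    centres of local-maximum bins of width ``bin_width``.
    """
    g = np.asarray(list(conductances), dtype=float)
    if g.size < 5:
        raise ValueError(
            "need at least 5 conductance values for peak finding; "
            "inspect the raw histogram instead")
    if np.ptp(g) == 0:
        return [float(g[0])]
    if method == "kde":
        kde = stats.gaussian_kde(g, bw_method="silverman")
        lo, hi = g.min(), g.max()
        pad = 3 * kde.factor * g.std(ddof=1)
        grid = np.linspace(lo - pad, hi + pad, 512)
        density = kde(grid)
        idx, _ = sps.find_peaks(density, prominence=0.05 * density.max())
        peaks = grid[idx]
    elif method == "hist":
        edges = np.arange(g.min() - bin_width, g.max() + 2 * bin_width,
                          bin_width)
        counts, edges = np.histogram(g, bins=edges)
        idx, _ = sps.find_peaks(counts, prominence=max(1, 0.05 * counts.max()))
        peaks = 0.5 * (edges[idx] + edges[idx + 1])
    else:
        raise ValueError(f"unknown peak method {method!r}")
    if peaks.size == 0:  # monotone density: fall back to the mode
        if method == "kde":
            peaks = np.array([grid[np.argmax(density)]])
        else:
            j = int(np.argmax(counts))
            peaks = np.array([0.5 * (edges[j] + edges[j + 1])])
    return sorted(float(p) for p in peaks)


def fit_calibration(entries: list[CalibrationEntry]) -> CalibrationModel:
    """Least-squares conductance→diameter line over calibration proteins."""
    if len(entries) < 2:
        raise ValueError("calibration needs at least 2 entries")
    g = np.array([e.conductance for e in entries])
    d = np.array([e.diameter for e in entries])
    if np.unique(g).size < 2:
        raise ValueError("calibration conductances are all identical; "
                         "the fit is singular")
    design = np.column_stack([g, np.ones_like(g)])
    coef, *_ = np.linalg.lstsq(design, d, rcond=None)
    resid = d - design @ coef
    return CalibrationModel(slope=float(coef[0]), intercept=float(coef[1]),
                            residual_ss=float(resid @ resid),
                            entries=list(entries))


def calibration_from_table(table: pd.DataFrame) -> CalibrationModel:
    """Fit the calibration from a table read by ``read_calibration_table``."""
    entries = [CalibrationEntry(str(r.protein), float(r.conductance_ns),
                                float(r.diameter_nm))
               for r in table.itertuples()]
    return fit_calibration(entries)


def estimate_diameter(conductance: float,
                      model: CalibrationModel) -> tuple[float, bool]:
    """Predicted pore diameter (nm) and an extrapolation flag.

    The flag is True when the conductance lies outside the calibration
    range.  A negative prediction is a calibration misuse and raises.
    """
    d = model.slope * conductance + model.intercept
    if d <= 0:
        raise ValueError(
            f"calibration predicts non-positive diameter {d:.3g} nm at "
            f"{conductance:.3g} nS")
    lo, hi = model.g_range
    return float(d), bool(conductance < lo or conductance > hi)


def assign_oligomer(diameter: float, table: pd.DataFrame) -> int:
    """Oligomer number whose modeled diameter is nearest ``diameter``.

    ``table`` has columns ``n`` and ``diameter_nm`` with diameters
    strictly increasing in n.  Ties at an exact midpoint go to the
    smaller n.
    """
    if len(table) == 0:
        raise ValueError("empty n-mer table")
    ns = table["n"].to_numpy()
    ds = table["diameter_nm"].to_numpy(dtype=float)
    err = np.abs(ds - diameter)
    # stable argmin + increasing-n order implements the smaller-n tie-break
    return int(ns[int(np.argmin(err))])


def rms_noise(trace: CurrentTrace, event: OpenEvent | tuple[int, int],
              window_s: float = 1.0) -> float:
    """Baseline-corrected open-state RMS noise (pA).

    ``sqrt(var_open − var_base)`` with unbiased (n−1) variances over the
    ~1 s windows before and after the pore opening.  As for the
    conductance, the open window starts once the opening transition is
    complete (three measured rise times in) so the ramp itself does not
    masquerade as noise.  Returns NaN when the open-state variance falls
    below the baseline variance (the quantity is then undefined).
    """
    rate = trace.sampling_rate
    skip = 0
    if isinstance(event, OpenEvent):
        start, end = event.start, event.end
        if np.isfinite(event.rise_time_ms):
            skip = min(int(round(3 * event.rise_time_ms * 1e-3 * rate)),
                       (end - start) // 2)
    else:
        start, end = event
    w = int(round(window_s * rate))
    base = trace.samples[max(0, start - w):start]
    open_seg = trace.samples[start + skip:min(end, start + skip + w)]
    if base.size < 2 or open_seg.size < 2:
        raise ValueError(
            f"rms_noise needs >= 2 samples in both the {window_s} s "
            f"baseline and open windows")
    var_base = float(np.var(base, ddof=1))
    var_open = float(np.var(open_seg, ddof=1))
    if var_open < var_base:
        return float("nan")
    return float(np.sqrt(var_open - var_base))


def normalize_rms(records: list[NoiseRecord]) -> tuple[list[NoiseRecord],
                                                       tuple[float, float]]:
    """Normalize RMS records to the fitted value at a 1 nS pore.

    Fits ``rms = a×G + b`` over all defined records and rescales each by
    ``(a·1 + b)/(a·G + b)``, so records lying on the line all map to the
    fitted 1 nS value.  Records where the fitted line is non-positive
    are flagged ``excluded`` and left unnormalized.  Returns the updated
    records and the fit coefficients (a, b).
    """
    usable = [r for r in records if r.defined]
    if len(usable) < 2 or len({r.conductance for r in usable}) < 2:
        raise ValueError("normalization needs >= 2 defined records with "
                         "distinct conductances")
    g = np.array([r.conductance for r in usable])
    y = np.array([r.rms for r in usable])
    design = np.column_stack([g, np.ones_like(g)])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    anchor = a * 1.0 + b
    for r in records:
        if not r.defined:
            r.excluded = True
            continue
        fitted = a * r.conductance + b
        if fitted <= 0:
            r.excluded = True
            r.normalized_rms = float("nan")
        else:
            r.excluded = False
            r.normalized_rms = r.rms * anchor / fitted
    return records, (float(a), float(b))


def low_noise_fraction(records: list[NoiseRecord],
                       threshold: float = 4.0) -> float:
    """Fraction of records with normalized RMS strictly below ``threshold``.

    The boundary value itself does not count as low-noise.
    """
    defined = [r for r in records
               if not r.excluded and np.isfinite(r.normalized_rms)]
    if not defined:
        raise ValueError("no records with a defined normalized RMS")
    return sum(r.normalized_rms < threshold for r in defined) / len(defined)
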