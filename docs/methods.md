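# Methods

This note documents the models, estimators and numerical choices behind
`peptidepore`, in the order a recording passes through them.

## Recording model and units

A recording is a uniformly sampled current series (pA) at a constant
applied potential (mV); time is implicit (index / sampling rate) and
resampling is unsupported. Defaults emulate a patch-clamp amplifier at
20 kHz sampling with a 4 kHz low-pass characteristic. With currents in
pA and voltages in mV, conductance is the bare ratio pA/mV = nS; all
durations are serialized in ms. The baseline (no open pore) is centred
on 0 pA, openings are positive excursions, and blockades move the
current from the open level back toward 0.

## Simulator

The simulator exists to provide ground truth: every analysis guarantee
in the test suite is a recovery statement against traces whose content
is known exactly.

**Noise.** Filtered white Gaussian noise: a white series of SD
`baseline_sd` (default 1.5 pA, a typical quiet bilayer at this
bandwidth) passed through a zero-phase 4th-order Butterworth low-pass at
the cutoff (default 4 kHz). Zero-phase filtering keeps event edges where
ground truth says they are. The filter reduces the white SD by an
empirical factor ≈ 0.60 at 4 kHz/20 kHz; tests that compare measured
SDs against injected ones always compare against the *filtered* oracle
(an independently filtered white series), never against the pre-filter
number. There is no 1/f term: the noise analyses downstream are
variance-based and make no spectral assumption beyond independence of
baseline and open-state noise sources.

**Openings.** The clean event waveform is added after the noise is
filtered, so levels and indices are exact. Rises are logistic ramps
whose 10–90% width equals the requested rise time, with the logistic
centred one rise-time after the event start (the onset then sits at
1.2% of amplitude at the ground-truth start index). Four archetypes:

- `step`: single level G×V, rise < 10 ms, modest open-state extra noise
  (0.5 + 2.0·G pA before filtering — noise grows mildly with
  conductance, the dependence the RMS normalization corrects for);
- `square_top`: staircase through ≥ 2 sub-levels with per-level dwells;
- `multi`: single level with open-state extra noise 15× the baseline SD,
  placing it firmly past the taxonomy's 10× spread criterion;
- `erratic`: logistic ramp slower than 10 ms (default 60 ms).

Multi and erratic events default to < 1 s: unstable pores and membrane
disruptions are transient, and this keeps the archetypes cleanly
separated from the 1 s long-event step rule. Scheduled events that
overlap or overrun the trace raise an error — nothing is clipped, so
ground truth always equals what is present.

**Blockades.** An open-pore trace sits at a constant level with
baseline-style noise. Arrivals are homogeneous Poisson; depths are
drawn around a mean blocking conductance (default 0.46 nS, SD 0.03);
dwells are log-normal — dwell times in nanopore sensing are
heavy-tailed — located so the *mean* dwell is 1.3 ms at the default
spread (σ_log = 0.5), since downstream centers are means. The
voltage dependence of the arrival rate is supplied per voltage (the
fixture suite doubles it per 50 mV step), not modeled parametrically.
Arrivals that would overlap or overrun are dropped, not truncated.

What the simulator does **not** emulate: membrane capacitance
transients, amplifier saturation, baseline drift, 1/f noise, gating
flicker, or multi-pore co-insertion. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise
model, not robustness to every artifact of real recordings.

## Opening detection

Baseline statistics are estimated robustly (median and 1.4826·MAD),
iterating three times with samples above median + 3 SD removed so the
estimate converges onto the baseline level even when open states occupy
a large fraction of the trace. Detection uses hysteresis: an event
begins when the current exceeds median + k·SD (k = 5) and ends when it
stays below median + 2.5·SD for at least a 5 ms debounce. Both edges
are then clamped to detection-threshold crossings, so baseline noise
excursions merged at the low threshold cannot pad the event with
near-baseline samples (unclamped tails were the dominant source of
step→multi confusions). Runs shorter than 1 ms are discarded as noise
excursions. Consequence: two openings separated by less than ~5 ms
merge into one event; the fixture suite spaces events by 1.5 s.

## Classification

- **Rise time** is measured 10–90% of the first-sub-level amplitude;
  crossing indices are the first samples at or above each threshold and
  the span is inclusive, so a one-sample jump reads as one sample
  period (0.05 ms at 20 kHz). The first-sub-level amplitude is the
  median over an early post-rise window (2.5–25% of the event, capped
  at 50–250 ms), past the rise of abrupt events but before later
  sub-levels of a staircase.
- **The 95% interval** of a window is the central percentile width
  (97.5th − 2.5th, linear interpolation) of the current *samples* — a
  distribution width, not a CI of the mean, which would shrink as 1/√n
  and trivialize the 10× criterion on long events.
- **Baseline reference** is the 1 s window immediately before the
  event (matching the RMS definition's pre-opening window); an event
  without a full pre-event window is an error naming the requirement.
- **Sub-levels** come from penalized binary segmentation of the
  open-state region (entered after skipping 3× the measured rise) into
  piecewise-constant means: the split with the largest SSE gain is
  accepted while the gain exceeds `penalty · σ̂² · log n`
  (σ̂ from the median absolute first difference / √2, penalty default
  5), each segment at least 50 ms; adjacent segments closer than
  10 pA are then merged. The penalty is calibrated so pure noise
  (max spurious gain ≈ 2σ²·log n) stays unsplit with margin while any
  staircase step of tens of pA over ≥ 50 ms is found.
- **Decision order**: erratic if rise > 10 ms; else step if the event
  is single-level and longer than 1 s (`long_event_forces_step`,
  default on — the long-event rule is taken to override the spread
  criterion for single-level signals); else multi if any sub-level's
  95% width exceeds 10× the baseline's; else square_top with ≥ 2
  sub-levels; else step. The four labels partition all detected events.

Event selection for population statistics keeps the 20 longest events
per measurement, pools them, and keeps the 50 longest overall; ties
break by earlier start index, then measurement key, making the
selection deterministic.

## Conductance, calibration, RMS noise

`open_conductance` averages the current over the first 1 s after the
opening *completes* — the window starts 3 measured rise-times into the
event — subtracts the pre-event baseline mean, and divides by the
voltage. Skipping the rise matters: including the partially risen
samples biases G low by ≈ 6×10⁻⁴·G, visible against the estimator's
~3×10⁻⁵ nS standard error at 50 seeds. The estimator is unbiased on
simulated steps (measured bias 0.8×10⁻⁵ ± 1.6×10⁻⁵ nS over 300 seeds).

Conductance histograms are summarized by Gaussian KDE peaks (Silverman
bandwidth, 512-point grid, 5%-prominence maxima) with a fixed-bin-width
histogram fallback; identical values short-circuit to that value.

The conductance→diameter calibration is an ordinary least-squares line
over (G, d) pairs of natural β-barrel proteins; predictions outside the
calibration range carry an extrapolation flag and a non-positive
predicted diameter is an error. The bundled six-protein table is
**synthetic**: the authoritative literature values live in the prior
work this approach builds on, so the shipped file is a placeholder
constructed to honour the characteristic correspondences
(0.4 nS ↔ 1.1 nm, 0.8 ↔ ~1.5, 1.1 ↔ 1.7) and is meant to be replaced.
Oligomer assignment is nearest-modeled-diameter in the n-mer table
(bundled: 5 → 1.1 nm, 6 → 1.5 nm, 7 → 1.7 nm), ties to the smaller n;
it is a step function of diameter with breakpoints at table midpoints.

RMS noise is √(var_open − var_base), unbiased (n−1) variances over the
1 s pre-opening and post-opening windows, the open window again
starting after the rise completes. When var_open < var_base the
quantity is undefined and reported as NaN. Because independent noise
variances add, the statistic recovers the (filtered) injected
open-state extra noise. Normalization fits rms = a·G + b over all
defined records and rescales each by (a + b)/(a·G + b) — records on
the fitted line all map to the fitted 1 nS value, and records at
G = 1 nS are fixed points. Records where the fitted line is
non-positive are flagged and excluded. The low-noise criterion is
strict: normalized RMS < 4 pA (the threshold is in pA after
normalization; the intercept is not forced through the origin).

## Blockades and bootstrap

A blockade spans the run of samples below open_level − threshold; the
threshold is an absolute pA drop or a fraction of the open level (the
pipeline default is 10% of the open level, which scales across
voltages, with a 2-sample re-entry debounce). Duration is the
deflection time from the mean open current; amplitude is the open mean
minus the event mean; blocking conductance is amplitude/voltage. The
translocation filter drops events with duration ≥ 3 ms (treating them
as pore-derived noise) and sub-resolution events (< 2 samples); the
filtered set is exactly the unfiltered set minus long events.

Event frequency is estimated per recording (count/duration) and
reported per voltage as mean ± SE across recordings — matching
error-bar semantics of mean ± SE — rather than pooling counts; for
recordings of equal length the two estimators coincide, and the
concatenation identity is tested.

The bootstrap is Monte-Carlo: B = 65,536 replicate means of 30 draws
with replacement under an explicit seed (the "entire space of
resamples" is astronomically larger; the fixed-B procedure is the
operative definition here). Its moments are checked against the
analytic values: grand mean → sample mean (tolerance
3·(s/√30)/√B) and replicate-mean SD → s·√((n−1)/n)/√30. Scatter
subsamples draw 300 replicate means without replacement. Condition
comparisons (control vs analyte) take both event sets as explicit
inputs — the package does not decide which events are pore noise.

## Peptide and CD utilities

Hydropathy scales ship as data files: Kyte–Doolittle (Ser −0.80,
Asp/Asn −3.50 — the S→D delta is −2.70) and Engelman GES transfer free
energies as originally published (kcal/mol, hydrophobic positive),
where Asn (−4.8) and Asp (−9.2) differ — the distinction that matters
when Asp-variants express and Asn-variants do not. Profiles use a
centred odd window that shrinks at the ends; positions are 1-based
everywhere, and substitutions verify the `from` residue before
applying.

The bundled peptide FASTA is a **synthetic stand-in** family: a
28-residue β-hairpin with serines at positions 5/11/17/23 and variants
substituting them to Asp/Asn (4 or 2 sites), reproducing the design
scheme — more substitutions, more hydrophilic — without claiming the
real sequences, which are not reproduced here.

MRE = (Y/1000)/(L·C·n) with Y in mdeg, L in cm, C in dmol·cm⁻³ and n
residues; the form is fixed by dimensional analysis of the declared
units (deg·cm²·dmol⁻¹·res⁻¹), the 1000 converting mdeg to deg.
Savitzky–Golay smoothing defaults to width 15, order 2, with
polynomial edge handling; interior outputs equal an explicit
local-quadratic fit to 1×10⁻⁹. Baseline subtraction removes the
buffer/disc blank and the expression-mixture blank element-wise on a
shared wavelength grid.

## Pipeline and reproducibility

One root seed fans out to every stage through `numpy.SeedSequence`
(children reduced mod 2³¹); outputs are plain TSV with the seed in a
header comment, floats at 10 significant digits, and a re-run with the
same config is byte-identical. The fixture suite is sized for
interactive use — five events per archetype trace, 30 s blockade traces
at four voltages — which keeps a full pipeline run to a few seconds
while giving every downstream statistic enough events to be
non-degenerate; recovery statements at tighter tolerances are made by
the dedicated tests at larger n.

## Known limitations

- The staircase segmenter assumes piecewise-constant levels; drifting
  or sloped open states will over-segment.
- Openings separated by less than the 5 ms debounce merge.
- The event detector assumes a single dominant baseline; recordings
  with large slow drift need external correction first.
- The calibration and n-mer tables bundled with the package are
  synthetic placeholders (see above) and must be replaced with
  literature values for quantitative pore-size claims.
- Exhaustive ("exact") bootstrap enumeration is out of scope; the
  Monte-Carlo procedure with B = 65,536 is the implemented definition.
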