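# Methods

## Signal model and pipeline order

A balance is a rigid plate on three load cells in a triangular layout.
The raw record is a text stream of four numeric columns per sample —
three dimensionless ADC-scale signals and elapsed time in microseconds.
Column order in such files is a logger convention; this package reads
signals-first/time-last by default with a `time_column` override, accepts
whitespace or comma delimiters, and writes whitespace. Timestamps are
elapsed from stream start; the wall-clock anchor (default 11:00) comes
from configuration because the files carry no absolute clock.
Non-monotone timestamps are a hard error, not a silent reorder: on this
kind of rig they indicate an acquisition fault, and reordering would
manufacture spurious weight changes.

The pipeline runs: calibration → signal-to-weight conversion → minute
binning → outlier filtering → weight changes → SWC/MWC/SD-WC/CV-WC per
minute → per-day baseline correction → quartile thresholds → domain
classification → tallies, heat maps, daily summaries.

## Calibration

Per cell, ordinary least squares of known mass (grams, the response) on
mean signal (the predictor): *y = ax + b*. The regression direction
follows the conversion use case — signals are observed, grams are wanted.
Diagnostics: r² and the standard error of the estimate
SEE = √(Σε²/(n−2)), undefined below three points. r² is reported, never
enforced; a warning fires below 0.999 (configurable) because on a healthy
load cell the calibration line is essentially exact, and deviation points
to electrical or mechanical defects rather than statistical noise.
Calibration pairs are means over a signal hold of ~10 s per known mass;
the averaging window is the operator's choice upstream of this package.

## Outlier filtering

Samples whose resultant weight deviates from the period mean by more
than k sample standard deviations (k = 2 default, n−1 denominator) are
dropped in a single pass — the bounds come from the unfiltered period
and are not re-iterated. The filtering period is the calendar minute by
default (local statistics track the nonstationary signal; a per-day mode
exists). The decision is made on the resultant weight and propagated to
all three cells to keep the per-cell sequences aligned. Removed points
are never interpolated; a weight-change pair spanning a removed point is
formed between the surviving neighbours. Sample SD was chosen over
population SD because per-minute counts are modest and the filter should
err toward keeping data.

Filtering interacts with the activity statistics: with k = 2 a few
percent of genuine large weight changes are trimmed along with spikes,
so phase-mean MWC sits a few percent below its unfiltered expectation.
The effect is nearly scale-equivariant, so *ratios* of phase means are
preserved much more accurately than the means themselves (observed in
the recovery tests: ~3–4% deficit per phase mean, <2% on their ratio
against a 3:1 ground truth).

## Minute statistics

Within each wall-clock minute (half-open convention: a boundary sample
belongs to the later minute; empty minutes are kept with zero samples),
consecutive-sample changes are computed without crossing minute
boundaries. A minute of N samples yields N−1 differences; MWC divides by
that count, preserving `swc == mwc * n_diffs` exactly. At ~2,400 samples
per minute the distinction between N and N−1 is negligible, but the
exact identity is worth keeping.

Cross-cell combination defaults to `per_cell_abs` — the per-step value is
|Δw₁| + |Δw₂| + |Δw₃| — because a weight shift from one cell to another
with zero net change is precisely what ambulation looks like on a
three-point plate, and the resultant-first alternative (|Δ(w₁+w₂+w₃)|)
is blind to it. For a load at a fixed position inside the support
triangle the two modes agree exactly (the per-cell shares are
nonnegative and sum to one). `resultant_first` remains a switch.

Zero- and one-sample minutes get swc = mwc = 0 rather than missing,
flagged via `n_samples` in QC output: the day-minimum correction needs a
value for every minute. CV-WC with zero mean change is reported missing
(NaN) and excluded from CV aggregates. SD-WC/CV-WC aggregation over
hours or phases is the arithmetic mean of per-minute values.

The single daily SPA value is the **mean** of corrected minute MWC over
the day's recorded minutes (not the sum: the mean stays comparable if a
day loses minutes to faults). Nadir and acrophase are the clock minutes
of the day's minimum and maximum corrected MWC, earliest minute on ties.
The across-days area under the curve uses the trapezoidal rule at 1-day
spacing; `relative_auc` expresses one AUC as a percentage of a reference
group's.

## Domains

Thresholds are the 25th/50th/75th percentiles of corrected minute MWC
pooled across all days and groups, with linear interpolation between
closest ranks (nearest-rank available; the choice is recorded in output
metadata). Classification follows the strict/inclusive boundary pattern
exactly as published — `< P25`, `< P50`, `≤ P75`, else — including the
asymmetric inclusive upper bound of the Moderate domain. The published
cut points (11.0, 16.8, 22.4) g are shipped as `REFERENCE_THRESHOLDS` for
classifying new data on the published scale. Gap and missing minutes are
excluded from threshold computation and tallies and are coded 0 in heat
maps.

## The simulator

The simulator generates raw streams the pipeline cannot distinguish from
rig output, with the latent truth retained for recovery tests.

**Statics.** A point mass at (x, y) splits across the cells by solving
vertical force balance plus two moment equations — equivalently the
barycentric coordinates of the position in the cell triangle times the
mass. Loads sum to the mass for any position; off-triangle positions
drive the far cell negative (the plate pulls up on it). Plate and cell
geometry default to a 60 × 47 cm plate with the apex cell at (55, 23.5)
and the base pair at x = 11 cm; the base pair's spread along y (8 and
39 cm, symmetric about mid-width) is a package convention, as only their
symmetry is physically constrained.

**Activity.** Activity is modelled as a per-step perturbation magnitude
of the total vertical force (grams-equivalent) — the minimal structure
the MWC statistic assumes, not a biomechanical gait model. Within a
minute the group's load position is held fixed and the total-weight
deviation alternates sign per sample with magnitude (b + mₜ)/2, where b
is the day's noise floor and mₜ ~ HalfNormal(σ) with σ the minute's
activity scale. The per-step absolute change is then exactly
b + (mₜ + mₜ₊₁)/2, giving the closed form

    E[minute MWC] = b + σ·√(2/π).

σ is σ_dark (default 24 g) in dark minutes and σ_light (default 8 g) in
light minutes — a 3:1 nocturnal contrast, on a scale that puts dark-phase
MWC near the published quartile band. Each minute is independently a
**rest minute** (σ = 0) with probability 0.05 in either phase: animals
are intermittently still, and these minutes are what the day-minimum
baseline correction actually finds — in a rest minute every change equals
b exactly, so the day minimum recovers the injected floor up to the rare
spike-removal artefact. Equal rest probability across phases keeps the
corrected phase-mean ratio at σ_dark/σ_light.

The position performs a bounded random walk (3 cm/min steps) **between**
minutes only. Since differences never cross minute boundaries,
relocation contributes nothing to MWC while still exercising the load
distribution; the walk region (x 12–36, y 18–29 cm) is the cage
interior's footprint placed inside the support triangle, so per-cell
shares stay nonnegative and `per_cell_abs` equals the resultant change
exactly. One pooled position stands in for the whole group, matching the
group-level nature of the measurement.

**Acquisition artefacts.** Sampling intervals are 1/f·(1 + U(−j, j)) with
f = 40 Hz and j = 0.2 — uniform multiplicative jitter reproducing the
sampling-rate fluctuation that motivates MWC over SWC. Spikes of ±200 g
are injected at rate 10⁻⁴ per sample (the 2-SD filter's target). The
per-day bias b is drawn uniformly in [0.5, 1.5] × 2 g. Signals are
produced by inverting per-cell calibration lines of HX711-like
magnitude, so analysis with the matching model recovers the simulated
loads to arithmetic precision. Everything is reproducible from one seed.

**What the simulator does not emulate:** individual-animal trajectories,
gait dynamics and vibration/resonance, ADC quantisation, temperature
drift within a day, and correlated rest bouts (rest minutes are i.i.d.).
Passing recovery tests therefore show the pipeline's statistics are
correct and stable under jitter, spikes and bias — not that any
particular biological effect size would be detected in real animals.

## Numerical and degenerate-input choices

- Percentile interpolation: linear between closest ranks (recorded in
  metadata); minimum four values.
- Outlier filter: zero-SD or length-<2 periods keep everything; k ≤ 0 is
  an error.
- Empty raw file → empty stream (not an error); empty day → error for
  correction/summary operations.
- Ties in nadir/acrophase → earliest minute.
- AUC needs ≥ 2 values; relative AUC needs a nonzero reference.
- CLI exit codes: 0 success, 1 validation, 2 I/O. Human-facing report
  values round to one decimal; machine CSVs keep full precision.

## Problem sizes in tests

Unit tests run on a compressed 2-hour schedule (one dark and one light
hour at 40 Hz, ~290k samples) so the suite completes in seconds;
the end-to-end recovery checks use one full default recording day
(22 h, ~3.2 M samples per cell) — large enough that phase means average
over ≥600 minutes, which is where the 5% recovery band for the 3:1
contrast is meaningful. The acceptance script simulates one fully
recorded hour at full rate.
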