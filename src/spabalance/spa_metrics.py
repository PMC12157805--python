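"""Minute-level SPA statistics: SWC, MWC, dispersion, baseline correction.

The elementary unit of spontaneous physical activity (SPA) on a weighing
balance is the weight change (WC): the absolute difference between
consecutive weight samples.  Two per-minute summaries are computed from
the within-minute WC sequence:

* **SWC** (sum of weight changes) — sensitive to the number of samples a
  minute happens to contain, which fluctuates on low-cost acquisition
  hardware;
* **MWC** (mean of weight changes) — the SWC divided by the number of
  consecutive-sample differences, robust to sampling-rate fluctuation.

A minute of N samples has N - 1 differences, so ``swc == mwc * n_diffs``
holds exactly on every minute.  Duplicating the change sequence (a
doubled sampling rate with the same per-step distribution) doubles SWC
and leaves MWC unchanged — the reason MWC exists.

Cross-cell combination: by default the per-step value is the sum of the
three per-cell absolute changes (``per_cell_abs``), which registers
weight redistribution across the plate with zero net change, i.e.
ambulation; ``resultant_first`` (absolute change of the summed weight)
is available as a switch.  Differences never span minute boundaries.

Dispersion complements: SD-WC (sample SD of the within-minute WCs) and
CV-WC (100 * SD / mean, reported missing when the mean is zero).  Two
minutes with identical MWC can carry different CV-WC — steady low-grade
motion versus a few large displacements.

Baseline-bias correction treats each day's quietest minute as the
system's noise floor for that day and subtracts its MWC from every
minute of the day, so the corrected daily minimum is exactly zero and
between-minute differences are untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, WeightSeries, convert_to_weight
from .preprocessing import MinuteGroup, effective_rate, filter_weight_series
from .raw_io import (
    DEFAULT_SCHEDULE,
    DEFAULT_START_CLOCK,
    LightSchedule,
    RawStream,
    format_clock,
)

__all__ = [
    "MinuteRecord",
    "DayProfile",
    "weight_changes",
    "swc",
    "mwc",
    "dispersion",
    "minute_record",
    "baseline_correct",
    "daily_value",
    "extremes",
    "auc_trapezoid",
    "relative_auc",
    "process_day",
    "minute_frame",
    "day_summary_frame",
]

COMBINE_MODES = ("per_cell_abs", "resultant_first")


@dataclass(frozen=True)
class MinuteRecord:
    """One recorded minute's SPA statistics.

    ``cv_wc`` is NaN when undefined (zero mean change); ``corrected_mwc``
    is NaN until the day has been baseline-corrected.  Minutes with
    fewer than 2 samples get swc = mwc = 0 (the day-minimum correction
    presumes a value for every minute) and are distinguishable through
    ``n_samples`` in QC output.
    """

    minute_stamp: int
    minute_of_day: int
    phase: str
    n_samples: int
    n_diffs: int
    swc: float
    mwc: float
    sd_wc: float
    cv_wc: float
    n_removed: int = 0
    corrected_mwc: float = math.nan


@dataclass
class DayProfile:
    """Ordered minute records of one recording day (1320 min by default).

    ``baseline_bias`` is NaN before correction and holds the subtracted
    day-minimum MWC afterwards.  Gap minutes are absent by construction.
    """

    day_id: str
    records: list[MinuteRecord]
    baseline_bias: float = math.nan
    balance_id: str = "balance"

    @property
    def corrected(self) -> bool:
        return not math.isnan(self.baseline_bias)

    def mwc_values(self, corrected: bool = False) -> np.ndarray:
        if corrected:
            if not self.corrected:
                raise ValueError("day has not been baseline-corrected")
            return np.array([r.corrected_mwc for r in self.records])
        return np.array([r.mwc for r in self.records])


# --------------------------------------------------------------------------
# per-minute primitives
# --------------------------------------------------------------------------

def weight_changes(group: MinuteGroup, combine: str = "per_cell_abs") -> np.ndarray:
    """Nonnegative per-step weight changes (grams) within one minute.

    ``per_cell_abs``: step value = |dw1| + |dw2| + |dw3|.
    ``resultant_first``: step value = |d(w1 + w2 + w3)|.
    A minute with fewer than 2 samples yields an empty sequence.
    """
    if combine not in COMBINE_MODES:
        raise ValueError(f"combine must be one of {COMBINE_MODES}, got {combine!r}")
    if group.n_samples < 2:
        return np.empty(0)
    if combine == "per_cell_abs":
        return np.abs(np.diff(group.w, axis=0)).sum(axis=1)
    return np.abs(np.diff(group.w_total))


def swc(changes: Sequence[float]) -> float:
    """Sum of weight changes (grams); 0 for an empty minute."""
    return float(np.sum(changes)) if len(changes) else 0.0


def mwc(changes: Sequence[float]) -> float:
    """Mean of weight changes (grams per sample step); 0 for an empty minute."""
    return float(np.mean(changes)) if len(changes) else 0.0


def dispersion(changes: Sequence[float]) -> tuple[float, float]:
    """(SD-WC, CV-WC) of the within-minute change sequence.

    SD is the sample SD (n-1); CV = 100 * SD / mean, NaN when the mean
    is zero (no information) or SD is undefined (< 2 changes).
    """
    x = np.asarray(changes, dtype=float)
    if x.size < 2:
        return math.nan, math.nan
    sd = float(x.std(ddof=1))
    m = float(x.mean())
    cv = 100.0 * sd / m if m != 0 else math.nan
    return sd, cv


def minute_record(
    group: MinuteGroup,
    schedule: LightSchedule = DEFAULT_SCHEDULE,
    combine: str = "per_cell_abs",
    *,
    phase_table: np.ndarray | None = None,
) -> MinuteRecord:
    """Assemble one minute's statistics from a (filtered) minute group."""
    if phase_table is None:
        phase_table = schedule.phase_lookup()
    changes = weight_changes(group, combine)
    sd, cv = dispersion(changes)
    return MinuteRecord(
        minute_stamp=group.minute_stamp,
        minute_of_day=group.minute_of_day,
        phase=str(phase_table[group.minute_of_day]),
        n_samples=group.n_samples,
        n_diffs=len(changes),
        swc=swc(changes),
        mwc=mwc(changes),
        sd_wc=sd,
        cv_wc=cv,
        n_removed=group.n_removed,
    )


# --------------------------------------------------------------------------
# day-level operations
# --------------------------------------------------------------------------

def baseline_correct(day: DayProfile) -> DayProfile:
    """Subtract the day's minimum minute MWC from every minute.

    Returns a new profile whose ``corrected_mwc`` has minimum exactly 0
    and whose ``baseline_bias`` records the subtracted value.  Rank
    order and pairwise differences between minutes are preserved.
    """
    if not day.records:
        raise ValueError(f"day {day.day_id!r} has no recorded minutes")
    bias = min(r.mwc for r in day.records)
    records = [replace(r, corrected_mwc=r.mwc - bias) for r in day.records]
    return DayProfile(
        day_id=day.day_id,
        records=records,
        baseline_bias=bias,
        balance_id=day.balance_id,
    )


def daily_value(day: DayProfile) -> float:
    """Single daily SPA value: mean corrected MWC over recorded minutes."""
    values = day.mwc_values(corrected=True)
    return float(values.mean())


def extremes(day: DayProfile) -> tuple[tuple[int, float], tuple[int, float]]:
    """((nadir minute-of-day, value), (acrophase minute-of-day, value)).

    Computed on corrected MWC; ties resolve to the earliest recorded
    minute.  On a corrected day the nadir value is 0 by construction.
    """
    values = day.mwc_values(corrected=True)
    i_min = int(np.argmin(values))  # argmin/argmax take the first of ties
    i_max = int(np.argmax(values))
    return (
        (day.records[i_min].minute_of_day, float(values[i_min])),
        (day.records[i_max].minute_of_day, float(values[i_max])),
    )


def auc_trapezoid(daily_values: Sequence[float], spacing: float = 1.0) -> float:
    """Trapezoidal area under the daily-value curve (grams * day)."""
    values = np.asarray(daily_values, dtype=float)
    if values.size < 2:
        raise ValueError("AUC needs at least 2 daily values")
    return float(np.trapezoid(values, dx=spacing))


def relative_auc(auc_a: float, auc_b: float) -> float:
    """``auc_a`` as a percentage of the reference ``auc_b`` (= 100%)."""
    if auc_b == 0:
        raise ValueError("reference AUC is zero")
    return 100.0 * auc_a / auc_b


# --------------------------------------------------------------------------
# pipeline orchestration
# --------------------------------------------------------------------------

def process_day(
    stream: RawStream,
    model: CalibrationModel,
    *,
    schedule: LightSchedule = DEFAULT_SCHEDULE,
    start_clock: int = DEFAULT_START_CLOCK,
    combine: str = "per_cell_abs",
    outlier_k: float = 2.0,
    outlier_period: str = "minute",
    correct: bool = True,
) -> DayProfile:
    """Raw stream -> calibrated, filtered, minute-binned day profile.

    Gap minutes (recording pause) are dropped; every other minute from
    the start clock through the end of the stream gets a record, empty
    minutes included.  ``correct=True`` applies baseline correction.
    """
    series = convert_to_weight(stream, model)
    groups, _ = filter_weight_series(series, start_clock, outlier_k, outlier_period)
    phase_table = schedule.phase_lookup()
    records = [
        minute_record(g, schedule, combine, phase_table=phase_table)
        for g in groups
        if phase_table[g.minute_of_day] != "gap"
    ]
    if not records:
        raise ValueError(f"stream {stream.day_id!r} produced no recorded minutes")
    day = DayProfile(
        day_id=stream.day_id, records=records, balance_id=stream.balance_id
    )
    return baseline_correct(day) if correct else day


# --------------------------------------------------------------------------
# tabular exports
# --------------------------------------------------------------------------

def minute_frame(days: Iterable[DayProfile]) -> pd.DataFrame:
    """Minute-level tidy table across days (one row per recorded minute)."""
    rows = []
    for day in days:
        for r in day.records:
            rows.append(
                {
                    "day_id": day.day_id,
                    "balance_id": day.balance_id,
                    "minute_stamp": r.minute_stamp,
                    "clock": format_clock(r.minute_of_day),
                    "minute_of_day": r.minute_of_day,
                    "phase": r.phase,
                    "n_samples": r.n_samples,
                    "n_removed": r.n_removed,
                    "swc": r.swc,
                    "mwc": r.mwc,
                    "sd_wc": r.sd_wc,
                    "cv_wc": r.cv_wc,
                    "corrected_mwc": r.corrected_mwc,
                }
            )
    return pd.DataFrame(rows)


def day_summary_frame(days: Iterable[DayProfile]) -> pd.DataFrame:
    """Day-level summary: daily value, baseline bias, nadir and acrophase."""
    rows = []
    for day in days:
        (nadir_min, nadir_val), (acro_min, acro_val) = extremes(day)
        rows.append(
            {
                "day_id": day.day_id,
                "balance_id": day.balance_id,
                "daily_value": daily_value(day),
                "baseline_bias": day.baseline_bias,
                "nadir_clock": format_clock(nadir_min),
                "nadir_value": nadir_val,
                "acrophase_clock": format_clock(acro_min),
                "acrophase_value": acro_val,
            }
        )
    return pd.DataFrame(rows)
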