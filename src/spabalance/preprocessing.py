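"""Outlier removal and wall-clock minute binning of weight series.

The outlier filter drops samples whose resultant weight deviates from
the period mean by more than ``k`` sample standard deviations (default
k = 2), in a single pass — bounds are computed once from the unfiltered
period.  The "period" defaults to the calendar minute, which tracks the
nonstationary signal; per-day filtering is available via
``filter_weight_series(..., period="day")``.  Removal is decided on the
resultant weight and propagated to all three cells, and removed points
are dropped (never interpolated): weight-change pairs spanning a removed
point are later formed between the surviving neighbours.

Minute binning assigns each sample to the wall-clock minute obtained
from the recording start clock plus the elapsed time, with the half-open
convention: a sample exactly on a minute boundary belongs to the later
minute.  Empty minutes are preserved with a sample count of zero so the
day profile keeps a value for every recorded minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import WeightSeries
from .raw_io import MINUTES_PER_DAY

__all__ = [
    "MinuteGroup",
    "outlier_mask",
    "remove_outliers",
    "filter_group",
    "filter_weight_series",
    "bin_by_minute",
    "effective_rate",
]

US_PER_MINUTE = 60_000_000


@dataclass
class MinuteGroup:
    """All samples of one wall-clock minute.

    ``minute_stamp`` counts minutes from midnight of the recording's
    first calendar day (so it can exceed 1439 on the post-midnight part
    of a recording day); ``minute_of_day`` is ``minute_stamp % 1440``.
    """

    minute_stamp: int
    t_us: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    w: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=float).reshape(len(self.t_us), 3)

    @property
    def n_samples(self) -> int:
        return len(self.t_us)

    @property
    def minute_of_day(self) -> int:
        return self.minute_stamp % MINUTES_PER_DAY

    @property
    def w_total(self) -> np.ndarray:
        return self.w.sum(axis=1)


def outlier_mask(values: Sequence[float], k: float = 2.0) -> np.ndarray:
    """Boolean keep-mask: False where |x - mean| > k * sample SD.

    Single pass: mean and SD (n-1 denominator) come from the full input.
    Sequences shorter than 2, or with zero SD, keep everything.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return np.ones(x.size, dtype=bool)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(x.size, dtype=bool)
    return np.abs(x - x.mean()) <= k * sd


def remove_outliers(
    values: Sequence[float], k: float = 2.0
) -> tuple[np.ndarray, int]:
    """Filtered copy of ``values`` plus the number of points removed."""
    x = np.asarray(values, dtype=float)
    keep = outlier_mask(x, k)
    return x[keep], int((~keep).sum())


def filter_group(group: MinuteGroup, k: float = 2.0) -> MinuteGroup:
    """Outlier-filter one minute on its resultant weight.

    The keep/drop decision is made on ``w_total`` and applied to all
    three cells, so the per-cell sequences stay aligned.
    """
    keep = outlier_mask(group.w_total, k)
    return MinuteGroup(
        minute_stamp=group.minute_stamp,
        t_us=group.t_us[keep],
        w=group.w[keep],
        n_removed=group.n_removed + int((~keep).sum()),
    )


def bin_by_minute(series: WeightSeries, start_clock: int) -> list[MinuteGroup]:
    """Split a weight series into wall-clock minutes.

    ``start_clock`` is the recording start as a minute-of-day (e.g. 660
    for 11:00); sample wall time = start_clock minutes + t_us.  Groups
    run from the start minute through the last sample's minute; minutes
    without samples appear with ``n_samples == 0``.
    """
    if len(series) == 0:
        return []
    stamps = start_clock + series.t_us // US_PER_MINUTE
    last = int(stamps[-1])
    # timestamps are sorted, so one searchsorted per boundary suffices
    edges = np.searchsorted(stamps, np.arange(start_clock, last + 2))
    groups = []
    for i, stamp in enumerate(range(start_clock, last + 1)):
        lo, hi = edges[i], edges[i + 1]
        groups.append(
            MinuteGroup(minute_stamp=stamp, t_us=series.t_us[lo:hi], w=series.w[lo:hi])
        )
    return groups


def filter_weight_series(
    series: WeightSeries,
    start_clock: int,
    k: float = 2.0,
    period: str = "minute",
) -> tuple[list[MinuteGroup], int]:
    """Bin into minutes and outlier-filter; returns (groups, total removed).

    ``period`` selects the window whose mean/SD define the outlier
    bounds: ``"minute"`` (default) or ``"day"`` (one bound set for the
    whole series).
    """
    if period not in ("minute", "day"):
        raise ValueError(f"period must be 'minute' or 'day', got {period!r}")
    groups = bin_by_minute(series, start_clock)
    if period == "day":
        keep = outlier_mask(series.w_total, k)
        filtered = WeightSeries(
            t_us=series.t_us[keep],
            w=series.w[keep],
            balance_id=series.balance_id,
            day_id=series.day_id,
            nominal_rate_hz=series.nominal_rate_hz,
        )
        removed = int((~keep).sum())
        regrouped = bin_by_minute(filtered, start_clock)
        # pad trailing empty minutes dropped with their samples
        stamps = {g.minute_stamp for g in regrouped}
        for g in groups:
            if g.minute_stamp not in stamps:
                regrouped.append(MinuteGroup(minute_stamp=g.minute_stamp))
        regrouped.sort(key=lambda g: g.minute_stamp)
        return regrouped, removed
    out = [filter_group(g, k) for g in groups]
    return out, sum(g.n_removed for g in out)


def effective_rate(group: MinuteGroup) -> float:
    """Realised sampling rate of a minute in Hz (n_samples / 60)."""
    return group.n_samples / 60.0
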