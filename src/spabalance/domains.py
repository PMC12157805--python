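"""Quartile-based SPA domain classification, tallies and heat maps.

Minute-level corrected MWC values are pooled across all days and groups
and cut at the 25th, 50th and 75th percentiles into four activity
domains: Very Low (1), Low (2), Moderate (3) and High (4).  The
classification rule is

    spa <  P25        -> 1 (VL)
    P25 <= spa < P50  -> 2 (L)
    P50 <= spa <= P75 -> 3 (M)   # upper bound inclusive
    spa >  P75        -> 4 (H)

Domain 3's inclusive upper bound is deliberately asymmetric with the
other strict bounds and is preserved verbatim.  The reference thresholds
(11.0, 16.8, 22.4) g ship as a named fixture so recorded data can be
classified against the published cut points without recomputation.

Tallies count minutes per domain per window (hourly, per-day per-phase,
or whole-experiment per-phase); within any fully recorded window the
four counts sum to the window's recorded minutes (60 for a full hour).
Heat maps arrange the domain codes as a (recorded-minute-of-day x day)
matrix, code 0 marking gap/missing minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .raw_io import DEFAULT_SCHEDULE, DEFAULT_START_CLOCK, LightSchedule
from .spa_metrics import DayProfile

__all__ = [
    "DomainThresholds",
    "REFERENCE_THRESHOLDS",
    "DOMAIN_NAMES",
    "compute_thresholds",
    "classify",
    "classify_series",
    "domain_series",
    "tally",
    "heatmap_matrix",
    "render_heatmap",
]

#: Domain code -> short name, in legend order VL -> H.  0 = missing/gap.
DOMAIN_NAMES = {0: "missing", 1: "VL", 2: "L", 3: "M", 4: "H"}


@dataclass(frozen=True)
class DomainThresholds:
    """P25/P50/P75 cut points on the corrected minute-MWC scale (grams)."""

    p25: float
    p50: float
    p75: float
    method: str = "linear"

    def __post_init__(self) -> None:
        if not (self.p25 <= self.p50 <= self.p75):
            raise ValueError(
                f"thresholds must be ordered: {self.p25}, {self.p50}, {self.p75}"
            )


#: Published cut points from the original two-cage mouse dataset (grams).
REFERENCE_THRESHOLDS = DomainThresholds(11.0, 16.8, 22.4, method="reference")


def compute_thresholds(
    values: Sequence[float], method: str = "linear"
) -> DomainThresholds:
    """Quartiles of the pooled corrected minute-MWC values.

    ``method`` is ``"linear"`` (interpolation between closest ranks,
    default) or ``"nearest"`` (nearest rank); it is recorded on the
    result so downstream metadata can echo the choice.
    """
    if method not in ("linear", "nearest"):
        raise ValueError(f"method must be 'linear' or 'nearest', got {method!r}")
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError(f"need >= 4 values for quartiles, got {x.size}")
    p25, p50, p75 = np.percentile(x, [25, 50, 75], method=method)
    return DomainThresholds(float(p25), float(p50), float(p75), method=method)


def classify(spa: float, thresholds: DomainThresholds) -> int:
    """Domain code (1-4) of one corrected minute-MWC value."""
    if spa < thresholds.p25:
        return 1
    if spa < thresholds.p50:
        return 2
    if spa <= thresholds.p75:  # inclusive upper bound of the moderate domain
        return 3
    return 4


def classify_series(
    spa: Sequence[float], thresholds: DomainThresholds
) -> np.ndarray:
    """Vectorised :func:`classify`; NaN inputs map to code 0 (missing)."""
    x = np.asarray(spa, dtype=float)
    codes = np.full(x.shape, 4, dtype=np.int8)
    codes[x <= thresholds.p75] = 3
    codes[x < thresholds.p50] = 2
    codes[x < thresholds.p25] = 1
    codes[np.isnan(x)] = 0
    return codes


def domain_series(
    days: Iterable[DayProfile], thresholds: DomainThresholds
) -> pd.DataFrame:
    """Per-minute domain codes across days.

    Columns: day_id, minute_stamp, minute_of_day, phase, spa
    (corrected MWC), code.  Gap minutes are absent from day profiles, so
    they do not appear here either.
    """
    rows = []
    for day in days:
        codes = classify_series(day.mwc_values(corrected=True), thresholds)
        for r, code in zip(day.records, codes):
            rows.append(
                {
                    "day_id": day.day_id,
                    "minute_stamp": r.minute_stamp,
                    "minute_of_day": r.minute_of_day,
                    "phase": r.phase,
                    "spa": r.corrected_mwc,
                    "code": int(code),
                }
            )
    return pd.DataFrame(rows)


def tally(series: pd.DataFrame, window: str = "hourly") -> pd.DataFrame:
    """Minutes (and percent) per domain per window.

    ``window``: ``"hourly"`` (hour-of-day across all days), ``"day_phase"``
    (each day split by dark/light) or ``"experiment_phase"`` (dark/light
    totals over the whole experiment).  Output columns: the window keys,
    ``min_VL .. min_H``, ``pct_VL .. pct_H`` and ``total_min``; per row
    the four domain counts sum to ``total_min``.
    """
    if window == "hourly":
        keys = ["hour"]
        df = series.assign(hour=series["minute_of_day"] // 60)
    elif window == "day_phase":
        keys = ["day_id", "phase"]
        df = series
    elif window == "experiment_phase":
        keys = ["phase"]
        df = series
    else:
        raise ValueError(
            "window must be 'hourly', 'day_phase' or 'experiment_phase', "
            f"got {window!r}"
        )
    counts = (
        df[df["code"] > 0]
        .groupby(keys + ["code"], observed=True)
        .size()
        .unstack("code", fill_value=0)
        .reindex(columns=[1, 2, 3, 4], fill_value=0)
    )
    out = counts.rename(columns={c: f"min_{DOMAIN_NAMES[c]}" for c in counts.columns})
    total = counts.sum(axis=1)
    out["total_min"] = total
    for c in (1, 2, 3, 4):
        out[f"pct_{DOMAIN_NAMES[c]}"] = 100.0 * counts[c] / total
    return out.reset_index()


def heatmap_matrix(
    series: pd.DataFrame,
    schedule: LightSchedule = DEFAULT_SCHEDULE,
    start_clock: int = DEFAULT_START_CLOCK,
) -> pd.DataFrame:
    """(recorded minute-of-day x day) matrix of domain codes.

    Rows follow recording order (start clock onward, gap minutes
    skipped): 1320 rows under the default schedule.  Cells with no
    record carry code 0.  Row index = clock minute-of-day, columns =
    day ids in first-appearance order.
    """
    minutes = schedule.recorded_minutes_of_day(start_clock)
    day_ids = list(dict.fromkeys(series["day_id"]))
    mat = pd.DataFrame(0, index=minutes, columns=day_ids, dtype=np.int8)
    for day_id, grp in series.groupby("day_id", sort=False):
        codes = pd.Series(
            grp["code"].to_numpy(), index=grp["minute_of_day"].to_numpy()
        )
        codes = codes[~codes.index.duplicated()]
        aligned = codes.reindex(minutes).fillna(0).astype(np.int8)
        mat[day_id] = aligned.to_numpy()
    mat.index.name = "minute_of_day"
    return mat


def render_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render the domain matrix as an image, one fixed colour per code.

    Legend order VL -> H; code 0 (missing/gap) in grey.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap
    from matplotlib.patches import Patch

    colors = ["#d9d9d9", "#2c7bb6", "#abd9e9", "#fdae61", "#d7191c"]
    cmap = ListedColormap(colors)
    norm = BoundaryNorm(np.arange(-0.5, 5.5), cmap.N)
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * matrix.shape[1] + 2), 6))
    ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap, norm=norm,
              interpolation="nearest")
    ax.set_xlabel("experimental day")
    ax.set_ylabel("recorded minute (from start of recording)")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    if title:
        ax.set_title(title)
    handles = [
        Patch(color=colors[c], label=DOMAIN_NAMES[c]) for c in (1, 2, 3, 4, 0)
    ]
    ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.01, 1),
              fontsize=7, title="SPA domain")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
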