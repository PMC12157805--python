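"""Per-load-cell linear calibration and signal-to-weight conversion.

Each load cell is calibrated independently: known masses (the study
design spans roughly 1.8 g to 215 g) are placed at the cell's mounting
point, the signal is held for ~10 s, and the (mean signal, known mass)
pairs are fit by ordinary least squares with mass as the response,

    y = a * x + b        (y grams, x signal units).

Fit quality is reported as r^2 and the standard error of the estimate
(SEE), the root mean square residual adjusted for the two fitted degrees
of freedom.  A cell's weight can be negative (off-triangle loads put the
plate under upward tension there); the resultant weight — the sum of the
three per-cell weights — recovers the applied mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .raw_io import RawStream

__all__ = [
    "LoadCellFit",
    "CalibrationModel",
    "WeightSeries",
    "CalibrationError",
    "fit_load_cell",
    "standard_error_of_estimate",
    "convert_to_weight",
    "read_calibration_pairs",
    "write_calibration_model",
    "read_calibration_model",
]

#: r^2 below this emits a warning: in practice low r^2 on a load cell
#: points to electrical or mechanical defects, not noise.
R2_WARN_THRESHOLD = 0.999


class CalibrationError(ValueError):
    """Calibration data insufficient or degenerate."""


@dataclass(frozen=True)
class LoadCellFit:
    """One cell's linear map and its diagnostics.

    ``see_g`` is NaN when fewer than 3 pairs were fit (no residual
    degrees of freedom).
    """

    a: float            # slope, grams per signal unit
    b: float            # intercept, grams
    r2: float
    see_g: float
    n_points: int

    def predict(self, signal: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(signal, dtype=float) + self.b

    def invert(self, mass_g: np.ndarray | float) -> np.ndarray | float:
        """Signal that would produce ``mass_g`` (used by the simulator)."""
        if self.a == 0:
            raise CalibrationError("zero slope cannot be inverted")
        return (np.asarray(mass_g, dtype=float) - self.b) / self.a


@dataclass(frozen=True)
class CalibrationModel:
    """The three per-cell fits of one balance."""

    cells: tuple[LoadCellFit, LoadCellFit, LoadCellFit]

    def __post_init__(self) -> None:
        if len(self.cells) != 3:
            raise CalibrationError("a balance has exactly 3 load cells")


@dataclass
class WeightSeries:
    """Calibrated weights: per-cell ``w`` (n, 3) and resultant ``w_total``.

    ``w_total[i] == w[i].sum()`` exactly at every sample; individual
    cells may read negative.
    """

    t_us: np.ndarray
    w: np.ndarray
    balance_id: str = "balance"
    day_id: str = "day0"
    nominal_rate_hz: float = 40.0

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=float).reshape(len(self.t_us), 3)

    @property
    def w_total(self) -> np.ndarray:
        return self.w.sum(axis=1)

    def __len__(self) -> int:
        return len(self.t_us)


def fit_load_cell(
    pairs: Sequence[tuple[float, float]], *, r2_warn: float = R2_WARN_THRESHOLD
) -> LoadCellFit:
    """OLS fit of mass (g) on mean signal from (known_mass_g, mean_signal) pairs.

    Requires >= 2 pairs with non-constant signal.  r^2 is reported, never
    enforced; values below ``r2_warn`` trigger a ``UserWarning``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise CalibrationError("need at least 2 (known_mass_g, mean_signal) pairs")
    mass, signal = arr[:, 0], arr[:, 1]
    if np.ptp(signal) == 0:
        raise CalibrationError("zero signal variance: cannot fit a line")
    res = stats.linregress(signal, mass)
    n = len(arr)
    if n >= 3:
        resid = mass - (res.slope * signal + res.intercept)
        see = math.sqrt(float(resid @ resid) / (n - 2))
    else:
        see = math.nan
    r2 = float(res.rvalue) ** 2
    if r2 < r2_warn:
        warnings.warn(
            f"load-cell calibration r^2 = {r2:.6f} < {r2_warn}: check for "
            "electrical or mechanical defects",
            UserWarning,
            stacklevel=2,
        )
    return LoadCellFit(
        a=float(res.slope), b=float(res.intercept), r2=r2, see_g=see, n_points=n
    )


def standard_error_of_estimate(
    fit: LoadCellFit, pairs: Sequence[tuple[float, float]]
) -> float:
    """SEE = sqrt(sum(residual^2) / (n - 2)) of ``fit`` on ``pairs`` (grams)."""
    arr = np.asarray(pairs, dtype=float)
    if len(arr) < 3:
        raise CalibrationError("SEE needs >= 3 pairs (n - 2 degrees of freedom)")
    mass, signal = arr[:, 0], arr[:, 1]
    resid = mass - fit.predict(signal)
    return math.sqrt(float(resid @ resid) / (len(arr) - 2))


def convert_to_weight(stream: RawStream, model: CalibrationModel) -> WeightSeries:
    """Apply the three per-cell linear maps to a raw stream.

    w_i = a_i * s_i + b_i per sample; the resultant is their sum.
    """
    a = np.array([c.a for c in model.cells])
    b = np.array([c.b for c in model.cells])
    return WeightSeries(
        t_us=stream.t_us,
        w=stream.signals * a + b,
        balance_id=stream.balance_id,
        day_id=stream.day_id,
        nominal_rate_hz=stream.nominal_rate_hz,
    )


# --------------------------------------------------------------------------
# tabular interfaces
# --------------------------------------------------------------------------

def read_calibration_pairs(path: str | Path) -> dict[int, list[tuple[float, float]]]:
    """Read a CSV of (cell_id, known_mass_g, mean_signal) into per-cell pairs."""
    df = pd.read_csv(path)
    required = {"cell_id", "known_mass_g", "mean_signal"}
    if not required.issubset(df.columns):
        raise CalibrationError(
            f"calibration CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    out: dict[int, list[tuple[float, float]]] = {}
    for cell_id, grp in df.groupby("cell_id"):
        out[int(cell_id)] = list(
            zip(grp["known_mass_g"].astype(float), grp["mean_signal"].astype(float))
        )
    return out


def write_calibration_model(model: CalibrationModel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": [1, 2, 3],
            "a": [c.a for c in model.cells],
            "b": [c.b for c in model.cells],
            "r2": [c.r2 for c in model.cells],
            "see_g": [c.see_g for c in model.cells],
            "n_points": [c.n_points for c in model.cells],
        }
    ).to_csv(path, index=False)


def read_calibration_model(path: str | Path) -> CalibrationModel:
    df = pd.read_csv(path).sort_values("cell_id")
    if len(df) != 3:
        raise CalibrationError(f"expected 3 cells in {path}, got {len(df)}")
    cells = tuple(
        LoadCellFit(
            a=float(r.a),
            b=float(r.b),
            r2=float(r.r2),
            see_g=float(r.see_g),
            n_points=int(r.n_points),
        )
        for r in df.itertuples()
    )
    return CalibrationModel(cells=cells)  # type: ignore[arg-type]
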