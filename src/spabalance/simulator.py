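"""Synthetic weighing-balance rig with known ground truth.

The simulator produces raw 4-column signal streams that exercise every
stage of the analysis pipeline — calibration inversion, outlier spikes,
sampling-rate jitter, dark/light activity contrast, per-day baseline
bias — together with the latent quantities that generated them, so
recovery can be tested end to end without hardware.

Physical model
--------------
The plate rests on three load cells in a triangular layout.  A static
load (cage + bedding + animals) at position (x, y) splits across the
cells by static equilibrium: vertical force balance plus two moment
equations, equivalently the barycentric coordinates of the position
with respect to the cell triangle scaled by the mass.  The three loads
always sum to the applied mass; positions outside the triangle drive at
least one cell negative (the plate pulls up on it).

Activity model
--------------
Activity is modelled as a per-step perturbation magnitude of the total
vertical force (grams-equivalent), not a biomechanical gait model: this
is the minimal structure the MWC statistic assumes.  Within a minute
the group's load position is held fixed and the total-weight deviation
alternates sign sample to sample with magnitude (bias + half-normal
draw) / 2, which makes the per-step absolute weight change exactly

    |dw| = bias + (m_t + m_{t+1}) / 2,     m ~ HalfNormal(sigma_phase)

so the expected minute MWC is ``bias + sigma * sqrt(2 / pi)`` in closed
form.  The position performs a bounded random walk *between* minutes
only; since differences never span minute boundaries, relocation does
not leak into the MWC.  A per-minute Bernoulli "rest" state (activity
scale zero, both phases) gives each day minutes whose MWC equals the
injected bias floor exactly, which is what the day-minimum baseline
correction estimates.  The walk is confined to a region inside the cell
triangle (the cage interior's footprint on the plate) so the per-cell
absolute changes sum exactly to the resultant change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, LoadCellFit
from .raw_io import (
    DEFAULT_SCHEDULE,
    DEFAULT_START_CLOCK,
    LightSchedule,
    MINUTES_PER_DAY,
    RawStream,
)

__all__ = [
    "RigGeometry",
    "DEFAULT_GEOMETRY",
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "CageGeometry",
    "distribute_load",
    "cage_geometry",
    "simulate_raw",
]

HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)  # E|N(0,1)|


@dataclass(frozen=True)
class RigGeometry:
    """Plate dimensions and load-cell coordinates (cm).

    Coordinate frame: origin at a plate corner, x along the 60 cm side,
    y along the 47 cm side.  LC3 is the triangle apex on the short side
    (23.5 cm from the edge, i.e. mid-width); LC1/LC2 form the base at
    49 cm from the opposite edge, symmetric about mid-width.  Their
    spread along y (8 and 39 cm) is a package convention.
    """

    plate_length_cm: float = 60.0
    plate_width_cm: float = 47.0
    lc1: tuple[float, float] = (11.0, 8.0)
    lc2: tuple[float, float] = (11.0, 39.0)
    lc3: tuple[float, float] = (55.0, 23.5)

    def __post_init__(self) -> None:
        (x1, y1), (x2, y2), (x3, y3) = self.lc1, self.lc2, self.lc3
        signed_area = 0.5 * ((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))
        if signed_area == 0:
            raise ValueError("load cells are collinear: no stable support triangle")
        for name, (x, y) in (("lc1", self.lc1), ("lc2", self.lc2), ("lc3", self.lc3)):
            if not (0 <= x <= self.plate_length_cm and 0 <= y <= self.plate_width_cm):
                raise ValueError(f"{name} at ({x}, {y}) lies outside the plate")

    @property
    def cells(self) -> np.ndarray:
        """(3, 2) array of cell coordinates in order LC1, LC2, LC3."""
        return np.array([self.lc1, self.lc2, self.lc3], dtype=float)

    def equilibrium_matrix(self) -> np.ndarray:
        """Coefficients of [force balance; moment about y; moment about x]."""
        c = self.cells
        return np.array([[1.0, 1.0, 1.0], c[:, 0], c[:, 1]])


DEFAULT_GEOMETRY = RigGeometry()


def distribute_load(
    position: tuple[float, float],
    mass_g: float,
    geometry: RigGeometry = DEFAULT_GEOMETRY,
) -> np.ndarray:
    """Static-equilibrium loads (LC1, LC2, LC3) for a point mass (grams).

    Solves vertical force balance plus the two moment equations — the
    barycentric coordinates of ``position`` w.r.t. the cell triangle,
    scaled by ``mass_g``.  The loads sum to ``mass_g`` exactly for any
    position; off-triangle positions give at least one negative load.
    """
    x, y = position
    rhs = np.array([mass_g, mass_g * x, mass_g * y])
    return np.linalg.solve(geometry.equilibrium_matrix(), rhs)


class CageGeometry(NamedTuple):
    floor_area_cm2: float
    fapa_cm2: float
    radius_cm: float


def cage_geometry(length_cm: float, width_cm: float, n_animals: int) -> CageGeometry:
    """Floor area, floor area per animal (FAPA) and equivalent-circle radius.

    FAPA = length * width / n; the radius of the circle with that area,
    sqrt(FAPA / pi), indexes the movement space available per animal.
    """
    if length_cm <= 0 or width_cm <= 0:
        raise ValueError("cage dimensions must be positive")
    if n_animals < 1:
        raise ValueError("need at least one animal")
    area = length_cm * width_cm
    fapa = area / n_animals
    return CageGeometry(area, fapa, math.sqrt(fapa / math.pi))


# --------------------------------------------------------------------------
# simulation configuration and ground truth
# --------------------------------------------------------------------------

#: Inverse-calibration lines (slope g/count, intercept g) used to turn
#: simulated loads back into ADC-scale signals; HX711-like magnitudes.
DEFAULT_CELL_LINES = (
    (0.0045, -12.0),
    (0.0043, -8.5),
    (0.0047, -15.0),
)


@dataclass
class SimulationConfig:
    """Generative parameters of one simulated rig recording.

    Defaults emulate the original study design: 40 Hz nominal sampling
    with +/-20% interval jitter, an inverted 12:12 cycle recorded 22 h/day
    (gap 09:00-11:00), ten mice pooled into one load position, dark-phase
    activity three times the light-phase scale, a small per-day baseline
    bias and rare large spikes.  ``sigma_dark``/``sigma_light`` are
    half-normal scales of the per-step weight change (grams-equivalent);
    ``daily_bias_g`` is the mean of the per-day noise floor (drawn
    uniformly in [0.5, 1.5] times this value); ``rest_prob`` is the
    per-minute probability (either phase) of a zero-activity minute.
    """

    n_days: int = 1
    schedule: LightSchedule = field(default_factory=lambda: DEFAULT_SCHEDULE)
    start_clock: int = DEFAULT_START_CLOCK
    static_mass_g: float = 600.0
    sigma_dark: float = 24.0
    sigma_light: float = 8.0
    nominal_rate_hz: float = 40.0
    jitter_frac: float = 0.2
    outlier_rate: float = 1e-4
    outlier_mag_g: float = 200.0
    daily_bias_g: float = 2.0
    rest_prob: float = 0.05
    cell_lines: tuple[tuple[float, float], ...] = DEFAULT_CELL_LINES
    geometry: RigGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)
    cage_length_cm: float = 28.3
    cage_width_cm: float = 17.5
    n_animals: int = 10
    walk_bounds: tuple[tuple[float, float], tuple[float, float]] = ((12.0, 36.0),
                                                                    (18.0, 29.0))
    walk_step_cm: float = 3.0
    balance_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_dark", "sigma_light", "jitter_frac", "outlier_rate",
                     "daily_bias_g", "rest_prob", "walk_step_cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_days < 1 or self.nominal_rate_hz <= 0 or self.static_mass_g <= 0:
            raise ValueError("n_days, nominal_rate_hz and static_mass_g must be positive")
        if not 0 <= self.jitter_frac < 1:
            raise ValueError("jitter_frac must be in [0, 1)")
        if self.sigma_dark < self.sigma_light:
            raise ValueError("expected sigma_dark >= sigma_light (nocturnal animals)")

    def calibration_model(self) -> CalibrationModel:
        """The exact linear maps a perfectly calibrated analysis would use."""
        cells = tuple(
            LoadCellFit(a=a, b=b, r2=1.0, see_g=0.0, n_points=0)
            for a, b in self.cell_lines
        )
        return CalibrationModel(cells=cells)  # type: ignore[arg-type]

    def to_metadata(self) -> dict:
        d = asdict(self)
        d["schedule"] = {
            "dark": list(self.schedule.dark_windows),
            "light": list(self.schedule.light_windows),
            "gap": list(self.schedule.gap_windows),
        }
        d["geometry"] = asdict(self.geometry)
        return d


@dataclass
class GroundTruth:
    """Latent state behind a simulation, for recovery tests.

    ``minutes`` has one row per recorded minute and day: day_id,
    minute_stamp, minute_of_day, phase, sigma (the minute's half-normal
    activity scale, 0 in rest minutes), rest, bias (that day's noise
    floor) and expected_mwc = bias + sigma * sqrt(2/pi).
    """

    minutes: pd.DataFrame
    day_bias: dict[str, float]

    def expected_phase_mean_mwc(self, phase: str) -> float:
        """Closed-form expected phase-mean minute MWC (grams)."""
        sub = self.minutes[self.minutes["phase"] == phase]
        if sub.empty:
            raise ValueError(f"no recorded minutes in phase {phase!r}")
        return float(sub["expected_mwc"].mean())


@dataclass
class SimulationResult:
    streams: list[RawStream]
    ground_truth: GroundTruth
    config: SimulationConfig


# --------------------------------------------------------------------------
# stream generation
# --------------------------------------------------------------------------

def _recording_minutes(config: SimulationConfig) -> np.ndarray:
    """Recorded minute-of-day sequence; requires one contiguous block."""
    minutes = config.schedule.recorded_minutes_of_day(config.start_clock)
    expected = (config.start_clock + np.arange(len(minutes))) % MINUTES_PER_DAY
    if not np.array_equal(minutes, expected):
        raise ValueError(
            "simulator needs a single contiguous recording block per day "
            "(gap adjacent to the start clock)"
        )
    return minutes


def _sample_times_s(config: SimulationConfig, duration_s: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Jittered sample times in seconds: t0 = 0, dt = (1/f)(1 + U(-j, j))."""
    mean_dt = 1.0 / config.nominal_rate_hz
    j = config.jitter_frac
    n_max = int(duration_s / (mean_dt * (1 - j) if j else mean_dt)) + 2
    dts = mean_dt * (1.0 + rng.uniform(-j, j, size=n_max))
    t = np.concatenate([[0.0], np.cumsum(dts)])
    return t[t < duration_s]


def simulate_raw(config: SimulationConfig) -> SimulationResult:
    """Generate per-day raw streams plus ground truth, reproducibly.

    The returned streams are in the canonical raw format (signals on the
    configured inverse-calibration lines, time in microseconds); running
    the analysis pipeline on them with ``config.calibration_model()``
    recovers the simulated loads to arithmetic precision.
    """
    rng = np.random.default_rng(config.seed)
    minutes_of_day = _recording_minutes(config)
    n_min = len(minutes_of_day)
    duration_s = 60.0 * n_min
    phase_table = config.schedule.phase_lookup()
    phases = phase_table[minutes_of_day]
    sigma_phase = np.where(phases == "dark", config.sigma_dark, config.sigma_light)

    A = config.geometry.equilibrium_matrix()
    a_line = np.array([a for a, _ in config.cell_lines])
    b_line = np.array([b for _, b in config.cell_lines])
    (x_lo, x_hi), (y_lo, y_hi) = config.walk_bounds

    streams: list[RawStream] = []
    truth_rows: list[pd.DataFrame] = []
    day_bias: dict[str, float] = {}
    pos = np.array([(x_lo + x_hi) / 2.0, (y_lo + y_hi) / 2.0])

    for d in range(config.n_days):
        day_id = f"day{d:02d}"
        bias = config.daily_bias_g * rng.uniform(0.5, 1.5)
        day_bias[day_id] = bias

        rest = rng.random(n_min) < config.rest_prob
        sigma_min = np.where(rest, 0.0, sigma_phase)

        # group position: bounded random walk, one step per minute
        steps = rng.normal(0.0, config.walk_step_cm, size=(n_min, 2))
        positions = np.empty((n_min, 2))
        for i in range(n_min):
            pos = pos + steps[i]
            pos[0] = min(max(pos[0], x_lo), x_hi)
            pos[1] = min(max(pos[1], y_lo), y_hi)
            positions[i] = pos
        rhs = np.vstack(
            [np.ones(n_min), positions[:, 0], positions[:, 1]]
        )
        bary = np.linalg.solve(A, rhs)  # (3, n_min), columns sum to 1

        t_s = _sample_times_s(config, duration_s, rng)
        n = len(t_s)
        minute_idx = np.minimum((t_s // 60.0).astype(np.int64), n_min - 1)

        # alternating-sign deviation: |step change| = bias + adjacent mean
        # of half-normal draws, so E[minute MWC] = bias + sigma*sqrt(2/pi)
        magnitude = bias + np.abs(rng.standard_normal(n)) * sigma_min[minute_idx]
        sign = 1.0 - 2.0 * (np.arange(n) % 2)
        w_total = config.static_mass_g + sign * magnitude / 2.0

        if config.outlier_rate > 0:
            spikes = rng.random(n) < config.outlier_rate
            w_total = w_total + spikes * rng.choice([-1.0, 1.0], size=n) \
                * config.outlier_mag_g

        loads = bary[:, minute_idx].T * w_total[:, None]  # (n, 3)
        signals = (loads - b_line) / a_line
        t_us = np.round(t_s * 1e6).astype(np.int64)

        streams.append(
            RawStream(
                balance_id=config.balance_id,
                day_id=day_id,
                nominal_rate_hz=config.nominal_rate_hz,
                t_us=t_us,
                signals=signals,
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "day_id": day_id,
                    "minute_stamp": config.start_clock + np.arange(n_min),
                    "minute_of_day": minutes_of_day,
                    "phase": phases,
                    "sigma": sigma_min,
                    "rest": rest,
                    "bias": bias,
                    "expected_mwc": bias + sigma_min * HALF_NORMAL_MEAN,
                }
            )
        )

    truth = GroundTruth(
        minutes=pd.concat(truth_rows, ignore_index=True), day_bias=day_bias
    )
    return SimulationResult(streams=streams, ground_truth=truth, config=config)
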