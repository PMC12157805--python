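"""Raw balance streams, the light/dark schedule, and text I/O.

A weighing-balance logger emits one plain-text file per balance per
recording day with four numeric columns per line: the three load-cell
signals (dimensionless, ADC scale) followed by the elapsed time in
microseconds.  Column order is a logger convention, not a standard;
``read_raw_stream`` defaults to signals-first/time-last and accepts a
``time_column`` override.  Both whitespace- and comma-delimited files are
read; the canonical format written here is whitespace-delimited.

Timestamps are elapsed microseconds from the start of the stream.  The
wall-clock anchor (the recording start time, 11:00 by default) is supplied
separately because raw files carry no absolute clock.

Live serial acquisition is out of scope: :class:`AcquisitionStub`
documents the interface a pySerial-style logger would implement, and
nothing in this package calls it.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "RawSample",
    "RawStream",
    "LightSchedule",
    "DEFAULT_SCHEDULE",
    "RawStreamError",
    "parse_clock",
    "format_clock",
    "read_raw_stream",
    "write_raw_stream",
    "assign_phase",
    "AcquisitionStub",
]

MINUTES_PER_DAY = 1440


class RawStreamError(ValueError):
    """Malformed or physically impossible raw-stream content."""


# --------------------------------------------------------------------------
# clock helpers
# --------------------------------------------------------------------------

def parse_clock(text: str) -> int:
    """Parse ``"HH:MM"`` into a minute-of-day integer in [0, 1440)."""
    m = re.fullmatch(r"(\d{1,2}):(\d{2})", text.strip())
    if not m:
        raise ValueError(f"not a HH:MM clock time: {text!r}")
    hh, mm = int(m.group(1)), int(m.group(2))
    if not (0 <= hh < 24 and 0 <= mm < 60):
        raise ValueError(f"clock time out of range: {text!r}")
    return hh * 60 + mm


def format_clock(minute_of_day: int) -> str:
    """Inverse of :func:`parse_clock`."""
    minute_of_day %= MINUTES_PER_DAY
    return f"{minute_of_day // 60:02d}:{minute_of_day % 60:02d}"


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RawSample:
    """One logger line: three load-cell signals and elapsed time."""

    t_us: int
    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        if self.t_us < 0:
            raise RawStreamError(f"negative timestamp: {self.t_us}")
        if not np.isfinite([self.s1, self.s2, self.s3]).all():
            raise RawStreamError("non-finite load-cell signal")


@dataclass
class RawStream:
    """An ordered stream of raw samples from one balance on one day.

    Internally the samples are stored as arrays (``t_us`` int64,
    ``signals`` float64 of shape (n, 3)); :meth:`samples` re-materialises
    :class:`RawSample` objects on demand.
    """

    balance_id: str = "balance"
    day_id: str = "day0"
    nominal_rate_hz: float = 40.0
    t_us: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    signals: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=np.int64)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.size == 0:
            self.signals = self.signals.reshape(0, 3)
        if self.nominal_rate_hz <= 0:
            raise RawStreamError("nominal_rate_hz must be positive")
        if self.signals.shape != (len(self.t_us), 3):
            raise RawStreamError(
                f"signals shape {self.signals.shape} does not match "
                f"{len(self.t_us)} timestamps"
            )
        if len(self.t_us) and self.t_us[0] < 0:
            raise RawStreamError("negative timestamp")
        self._check_monotone()

    def _check_monotone(self) -> None:
        if len(self.t_us) < 2:
            return
        bad = np.nonzero(np.diff(self.t_us) <= 0)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise RawStreamError(
                f"timestamps not strictly increasing at sample index {i} "
                f"(t_us[{i - 1}]={self.t_us[i - 1]}, t_us[{i}]={self.t_us[i]}); "
                "this indicates an acquisition fault, refusing to reorder"
            )

    def __len__(self) -> int:
        return len(self.t_us)

    def samples(self) -> Iterator[RawSample]:
        for t, (s1, s2, s3) in zip(self.t_us, self.signals):
            yield RawSample(int(t), float(s1), float(s2), float(s3))


@dataclass(frozen=True)
class LightSchedule:
    """Daily lamp schedule as minute-of-day windows.

    Windows are half-open ``[start, end)`` minute-of-day intervals.  The
    three window sets must be disjoint and tile the 24-h day.  The default
    profile mirrors an inverted 12:12 cycle with a daily husbandry pause:
    dark (lamps off, animals active) 11:00-18:59 and 07:00-08:59, light
    (lamps on) 19:00-06:59, gap (recording paused) 09:00-10:59.
    """

    dark_windows: tuple[tuple[int, int], ...] = ((660, 1140), (420, 540))
    light_windows: tuple[tuple[int, int], ...] = ((1140, 1440), (0, 420))
    gap_windows: tuple[tuple[int, int], ...] = ((540, 660),)

    def __post_init__(self) -> None:
        cover = np.zeros(MINUTES_PER_DAY, dtype=np.uint8)
        for windows in (self.dark_windows, self.light_windows, self.gap_windows):
            for start, end in windows:
                if not (0 <= start < end <= MINUTES_PER_DAY):
                    raise ValueError(f"window ({start}, {end}) outside the day")
                cover[start:end] += 1
        if (cover > 1).any():
            raise ValueError("schedule windows overlap")
        if (cover == 0).any():
            m = int(np.argmin(cover))
            raise ValueError(f"schedule leaves minute {format_clock(m)} unassigned")

    @classmethod
    def from_clock_ranges(
        cls,
        dark: Sequence[str],
        light: Sequence[str],
        gap: Sequence[str] = (),
    ) -> "LightSchedule":
        """Build from ``"HH:MM-HH:MM"`` ranges, end minute inclusive.

        ``"11:00-18:59"`` covers minutes 660..1139.  Ranges wrapping
        midnight (``"19:00-06:59"``) are split into two windows.
        """

        def convert(ranges: Sequence[str]) -> tuple[tuple[int, int], ...]:
            out: list[tuple[int, int]] = []
            for r in ranges:
                lo_s, hi_s = r.split("-")
                lo, hi = parse_clock(lo_s), parse_clock(hi_s) + 1
                if lo < hi:
                    out.append((lo, hi))
                else:  # wraps midnight
                    out.append((lo, MINUTES_PER_DAY))
                    out.append((0, hi))
            return tuple(out)

        return cls(convert(dark), convert(light), convert(gap))

    def phase_lookup(self) -> np.ndarray:
        """Length-1440 array of ``'dark' | 'light' | 'gap'`` per minute."""
        table = np.empty(MINUTES_PER_DAY, dtype="U5")
        for label, windows in (
            ("dark", self.dark_windows),
            ("light", self.light_windows),
            ("gap", self.gap_windows),
        ):
            for start, end in windows:
                table[start:end] = label
        return table

    def minutes_per_phase(self) -> dict[str, int]:
        table = self.phase_lookup()
        return {p: int((table == p).sum()) for p in ("dark", "light", "gap")}

    def recorded_minutes_of_day(self, start_clock: int) -> np.ndarray:
        """Non-gap minute-of-day values in recording order from start_clock."""
        table = self.phase_lookup()
        order = (np.arange(MINUTES_PER_DAY) + start_clock) % MINUTES_PER_DAY
        return order[table[order] != "gap"]


DEFAULT_SCHEDULE = LightSchedule()

#: Recording starts at 11:00 unless configured otherwise.
DEFAULT_START_CLOCK = 660


def assign_phase(clock_minute: int, schedule: LightSchedule = DEFAULT_SCHEDULE) -> str:
    """Map a minute-of-day (0..1439) to ``'dark'``, ``'light'`` or ``'gap'``."""
    return str(schedule.phase_lookup()[clock_minute % MINUTES_PER_DAY])


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

_Source = Union[str, Path, TextIO]

_CANONICAL_FMT = "{s1:.6f} {s2:.6f} {s3:.6f} {t:d}"


def _open(source: _Source, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_raw_stream(
    source: _Source,
    nominal_rate_hz: float = 40.0,
    *,
    balance_id: str = "balance",
    day_id: str = "day0",
    time_column: str = "last",
) -> RawStream:
    """Read a 4-column raw stream (3 signals + time in microseconds).

    ``time_column`` is ``"last"`` (default: s1 s2 s3 t) or ``"first"``
    (t s1 s2 s3).  Whitespace- and comma-delimited lines are both
    accepted; blank lines are ignored.  Malformed lines raise
    :class:`RawStreamError` naming the 1-based line number; non-monotone
    timestamps raise naming the first offending sample index.  An empty
    source yields an empty stream.
    """
    if time_column not in ("last", "first"):
        raise ValueError(f"time_column must be 'last' or 'first', got {time_column!r}")
    fh, close = _open(source, "r")
    try:
        times: list[int] = []
        sigs: list[tuple[float, float, float]] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 4:
                raise RawStreamError(
                    f"line {lineno}: expected 4 numeric fields, got {len(fields)}"
                )
            try:
                values = [float(f) for f in fields]
            except ValueError:
                raise RawStreamError(
                    f"line {lineno}: non-numeric field in {line!r}"
                ) from None
            if time_column == "last":
                s1, s2, s3, t = values
            else:
                t, s1, s2, s3 = values
            times.append(int(round(t)))
            sigs.append((s1, s2, s3))
    finally:
        if close:
            fh.close()
    return RawStream(
        balance_id=balance_id,
        day_id=day_id,
        nominal_rate_hz=nominal_rate_hz,
        t_us=np.asarray(times, dtype=np.int64),
        signals=np.asarray(sigs, dtype=float).reshape(len(times), 3),
    )


def write_raw_stream(stream: RawStream, sink: _Source) -> None:
    """Write the canonical 4-column text format (signals first, time last)."""
    fh, close = _open(sink, "w")
    try:
        for t, (s1, s2, s3) in zip(stream.t_us, stream.signals):
            fh.write(_CANONICAL_FMT.format(s1=s1, s2=s2, s3=s3, t=int(t)) + "\n")
    finally:
        if close:
            fh.close()


class AcquisitionStub:
    """Interface stub for a live serial logger (not implemented here).

    A hardware acquisition front end would open a serial port, read the
    amplifier's framed samples and append canonical 4-column lines to a
    text sink.  This package analyses such files; it does not acquire
    them, so every method raises ``NotImplementedError``.
    """

    def open(self, port: str, baud: int = 115200) -> None:  # pragma: no cover
        raise NotImplementedError("live acquisition is out of scope")

    def record(self, sink: TextIO, duration_s: float) -> None:  # pragma: no cover
        raise NotImplementedError("live acquisition is out of scope")
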