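"""Programmable light-stimulation schedules.

An optogenetic stimulation protocol is an ordered set of light-on intervals
on a discrete time grid.  Two protocol families are supported:

* interval protocols — a fixed exposure followed by a fixed off period,
  repeated (e.g. 1 s on / 8 s off for single-animal imaging), and
* pulsed exercise regimens — short pulses at a fixed frequency delivered in
  bursts (e.g. 10 ms pulses at 20 Hz for the first 30 s of every minute,
  for an hour of whole-population "neuronal exercise").

Time is held internally as integer ticks of ``time_resolution`` (default
5 ms, the exposure resolution of the LED/relay hardware the schedules are
designed for), so hour-long pulse trains accumulate no float drift and the
total on-time is exact.  Intervals are half-open ``[t_on, t_off)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "DEFAULT_RESOLUTION_S",
    "LightSchedule",
    "PulseRegimen",
    "build_pulse_regimen",
    "build_interval_protocol",
    "read_schedule_csv",
]

DEFAULT_RESOLUTION_S = 0.005


def _to_ticks(t: float, resolution: float, name: str = "time") -> int:
    """Quantize a time in seconds to the nearest integer tick."""
    if not math.isfinite(t):
        raise ValueError(f"{name} must be finite, got {t!r}")
    return int(round(t / resolution))


@dataclass(frozen=True)
class LightSchedule:
    """Ordered, non-overlapping light-on intervals on a fixed time grid.

    Parameters
    ----------
    intervals_ticks :
        Sorted tuple of ``(on_tick, off_tick)`` pairs, half-open, pairwise
        disjoint, with ``0 <= on < off <= total_ticks``.
    total_ticks :
        Schedule duration in ticks.
    time_resolution :
        Tick size in seconds.
    """

    intervals_ticks: tuple[tuple[int, int], ...]
    total_ticks: int
    time_resolution: float = DEFAULT_RESOLUTION_S

    def __post_init__(self) -> None:
        if self.time_resolution <= 0:
            raise ValueError("time_resolution must be positive")
        if self.total_ticks < 0:
            raise ValueError("total_ticks must be non-negative")
        prev_off = 0
        for on, off in self.intervals_ticks:
            if not (0 <= on < off <= self.total_ticks):
                raise ValueError(
                    f"interval ({on}, {off}) ticks violates "
                    f"0 <= t_on < t_off <= {self.total_ticks}"
                )
            if on < prev_off:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_off = off

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[float, float]],
        total_duration: float,
        time_resolution: float = DEFAULT_RESOLUTION_S,
    ) -> "LightSchedule":
        """Build a schedule from ``(t_on, t_off)`` pairs in seconds.

        Times are quantized to the nearest tick of ``time_resolution``.
        Intervals that quantize to zero width are rejected.
        """
        ticks = []
        for t_on, t_off in intervals:
            on = _to_ticks(t_on, time_resolution, "t_on")
            off = _to_ticks(t_off, time_resolution, "t_off")
            if off <= on:
                raise ValueError(
                    f"interval ({t_on}, {t_off}) s quantizes to zero/negative "
                    f"width at resolution {time_resolution} s"
                )
            ticks.append((on, off))
        ticks.sort()
        return cls(
            intervals_ticks=tuple(ticks),
            total_ticks=_to_ticks(total_duration, time_resolution, "total_duration"),
            time_resolution=time_resolution,
        )

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    @property
    def total_duration(self) -> float:
        """Schedule duration in seconds."""
        return self.total_ticks * self.time_resolution

    @property
    def n_intervals(self) -> int:
        return len(self.intervals_ticks)

    @property
    def intervals(self) -> list[tuple[float, float]]:
        """Intervals as ``(t_on, t_off)`` in seconds."""
        r = self.time_resolution
        return [(on * r, off * r) for on, off in self.intervals_ticks]

    @property
    def onsets(self) -> list[float]:
        """Light-on onset times in seconds."""
        return [on * self.time_resolution for on, _ in self.intervals_ticks]

    @property
    def total_on_time(self) -> float:
        """Summed on-time in seconds (exact on the tick grid)."""
        return sum(off - on for on, off in self.intervals_ticks) * self.time_resolution

    def light_state(self, t: float) -> bool:
        """Return True iff the light is on at time ``t`` (seconds).

        Intervals are half-open: at ``t == t_off`` the light is off.
        """
        if not 0 <= t <= self.total_duration:
            raise ValueError(
                f"t={t} outside schedule range [0, {self.total_duration}]"
            )
        r = self.time_resolution
        # binary search over onsets
        lo, hi = 0, len(self.intervals_ticks)
        while lo < hi:
            mid = (lo + hi) // 2
            if self.intervals_ticks[mid][0] * r <= t:
                lo = mid + 1
            else:
                hi = mid
        if lo == 0:
            return False
        on, off = self.intervals_ticks[lo - 1]
        return on * r <= t < off * r

    def shifted(self, offset: float) -> "LightSchedule":
        """Circularly shift all intervals by ``offset`` seconds (mod duration).

        Used to estimate chance-level stimulus/event coincidence: shifting
        the schedule destroys any true temporal coupling while preserving
        its on/off statistics.
        """
        if self.total_ticks == 0:
            return self
        d = _to_ticks(offset, self.time_resolution, "offset") % self.total_ticks
        pieces = []
        for on, off in self.intervals_ticks:
            on, off = on + d, off + d
            if off <= self.total_ticks:
                pieces.append((on, off))
            elif on >= self.total_ticks:
                pieces.append((on - self.total_ticks, off - self.total_ticks))
            else:  # wraps
                pieces.append((on, self.total_ticks))
                pieces.append((0, off - self.total_ticks))
        pieces.sort()
        # merge any adjacency created at the wrap point
        merged: list[list[int]] = []
        for on, off in pieces:
            if merged and on <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], off)
            else:
                merged.append([on, off])
        return LightSchedule(
            tuple((a, b) for a, b in merged), self.total_ticks, self.time_resolution
        )

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.intervals)

    # ------------------------------------------------------------------
    # export
    # ------------------------------------------------------------------
    def to_csv(self, destination) -> None:
        """Write the schedule as a two-column CSV ``t_on_s,t_off_s``.

        A leading ``#`` comment records the tick resolution and total
        duration so the file round-trips losslessly through
        :func:`read_schedule_csv`.
        """
        decimals = 3 if self.time_resolution >= 1e-3 else 6
        lines = [
            f"# wormpulse-schedule-v1 resolution_s={self.time_resolution:.6g} "
            f"total_s={self.total_duration:.6f}",
            "t_on_s,t_off_s",
        ]
        for t_on, t_off in self.intervals:
            lines.append(f"{t_on:.{decimals}f},{t_off:.{decimals}f}")
        text = "\n".join(lines) + "\n"
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w", encoding="utf-8") as fh:
                fh.write(text)


def read_schedule_csv(
    source,
    time_resolution: float | None = None,
    total_duration: float | None = None,
) -> LightSchedule:
    """Read a schedule CSV written by :meth:`LightSchedule.to_csv`.

    ``time_resolution``/``total_duration`` override the file's metadata
    comment; at least one source for each must be available.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    res, total = time_resolution, total_duration
    rows: list[tuple[float, float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                if token.startswith("resolution_s=") and res is None:
                    res = float(token.split("=", 1)[1])
                elif token.startswith("total_s=") and total is None:
                    total = float(token.split("=", 1)[1])
            continue
        if line.lower().startswith("t_on"):
            continue
        a, b = line.split(",")
        rows.append((float(a), float(b)))
    if res is None:
        raise ValueError("time_resolution not given and absent from file metadata")
    if total is None:
        total = max((b for _, b in rows), default=0.0)
    return LightSchedule.from_intervals(rows, total, res)


# export_schedule is the operation name used by the CLI; kept as a thin
# function so callers need not know it is a method.
def export_schedule(schedule: LightSchedule, destination) -> None:
    schedule.to_csv(destination)


@dataclass(frozen=True)
class PulseRegimen:
    """A burst-structured pulse train for whole-population exercise.

    ``pulse_width`` s pulses at ``pulse_frequency`` Hz for the first
    ``burst_duration`` s of every ``burst_period`` s, over
    ``total_duration`` s.
    """

    pulse_width: float
    pulse_frequency: float
    burst_duration: float
    burst_period: float
    total_duration: float

    def __post_init__(self) -> None:
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if self.pulse_frequency <= 0:
            raise ValueError("pulse_frequency must be positive")
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")
        if self.burst_period <= 0:
            raise ValueError("burst_period must be positive")
        if self.total_duration < 0:
            raise ValueError("total_duration must be non-negative")
        if self.pulse_width > 1.0 / self.pulse_frequency + 1e-12:
            raise ValueError(
                "pulse_width exceeds the pulse period 1/pulse_frequency"
            )
        if self.burst_duration > self.burst_period + 1e-12:
            raise ValueError("burst_duration exceeds burst_period")


def build_pulse_regimen(
    regimen: PulseRegimen, time_resolution: float = DEFAULT_RESOLUTION_S
) -> LightSchedule:
    """Expand a :class:`PulseRegimen` into an explicit :class:`LightSchedule`.

    Pulses start at spacing ``1/pulse_frequency`` from the start of each
    burst window ``[k*burst_period, k*burst_period + burst_duration)``.  A
    pulse is emitted iff its start lies inside the burst window; a pulse
    extending past the window (or the schedule end) is clipped there.
    """
    r = time_resolution
    width = _to_ticks(regimen.pulse_width, r, "pulse_width")
    if width < 1:
        raise ValueError(
            f"pulse_width {regimen.pulse_width} s is below the time "
            f"resolution {r} s"
        )
    spacing = _to_ticks(1.0 / regimen.pulse_frequency, r, "pulse period")
    if spacing < 1:
        raise ValueError("pulse_frequency too high for the time resolution")
    burst_dur = _to_ticks(regimen.burst_duration, r, "burst_duration")
    burst_per = _to_ticks(regimen.burst_period, r, "burst_period")
    total = _to_ticks(regimen.total_duration, r, "total_duration")

    intervals: list[tuple[int, int]] = []
    k = 0
    while k * burst_per < total:
        start = k * burst_per
        window_end = min(start + burst_dur, total)
        p = start
        while p < window_end:
            intervals.append((p, min(p + width, window_end)))
            p += spacing
        k += 1
    return LightSchedule(tuple(intervals), total, r)


def build_interval_protocol(
    on_time: float,
    off_time: float,
    total_duration: float,
    time_resolution: float = DEFAULT_RESOLUTION_S,
) -> LightSchedule:
    """Periodic exposure protocol: ``on_time`` s on, ``off_time`` s off.

    Exposures start at t = 0 with period ``on_time + off_time``; a final
    partial exposure is clipped at ``total_duration``, not dropped.  With
    ``off_time == 0`` consecutive exposures abut into continuous light.
    """
    if on_time <= 0:
        raise ValueError("on_time must be positive")
    if off_time < 0:
        raise ValueError("off_time must be non-negative")
    if total_duration < 0:
        raise ValueError("total_duration must be non-negative")
    r = time_resolution
    on = _to_ticks(on_time, r, "on_time")
    if on < 1:
        raise ValueError(f"on_time {on_time} s is below the time resolution {r} s")
    period = on + _to_ticks(off_time, r, "off_time")
    total = _to_ticks(total_duration, r, "total_duration")
    intervals = []
    p = 0
    while p < total:
        intervals.append((p, min(p + on, total)))
        p += period
    return LightSchedule(tuple(intervals), total, r)
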