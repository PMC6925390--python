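"""Piecewise-linear tiredness model over wearable sleep episodes.

The model assigns every awake minute a scalar tiredness level (TL).  A
*new-day sleep* — an episode that spans a calendar-day boundary, or that
starts on the day after the previous new-day sleep ended — resets the
trajectory: at its end (the wake time) TL restarts at

    TL(wake) = max(threshold_tl - gamma, 0)

where gamma is the episode's duration plus the durations of any naps
credited to it (naps are every other episode; each is credited to the
*following* new-day sleep).  TL then rises linearly at 3/8 TL-units per
minute, so a fully rested subject (gamma >= 360 min, i.e. 6 h) crosses
the deprivation threshold of 360 exactly 16 h after waking.  A subject is
sleep deprived whenever TL >= threshold_tl (the onset instant counts as
deprived).

Long sensor silences are treated as missing data: if no episode starts
within ``max_awake`` (28 h) of the previous episode's end, the stretch
from hour 28 until the next sleep is an *exclusion window*, and the
trajectory's horizon is the last episode's end plus 28 h, after which all
time is excluded.

All intervals are half-open ``[start, end)`` at minute resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_ingest import SleepEpisode, SleepSchedule
from .timeutil import day_index, format_ts

logger = logging.getLogger(__name__)

#: sentinel results of :func:`tiredness_at`
ASLEEP = "asleep"
EXCLUDED = "excluded"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class TirednessParams:
    """Constants of the tiredness model.

    threshold_tl
        TL at and above which the subject is sleep deprived (360, the
        number of minutes in the 6-h deprivation definition).
    slope
        TL rise per awake minute; fixed at threshold_tl / hours_to_sld_rested
        = 360/960 = 3/8.
    min_sleep
        minutes of sleep defining deprivation (360 = 6 h).
    hours_to_sld_rested
        minutes a fully rested subject stays below threshold (960 = 16 h).
    max_awake
        minutes after which a sleep gap is treated as sensor dropout
        (1680 = 28 h).
    """

    threshold_tl: float = 360.0
    slope: float = 3.0 / 8.0
    min_sleep: int = 360
    hours_to_sld_rested: int = 960
    max_awake: int = 1680

    def __post_init__(self) -> None:
        if min(self.threshold_tl, self.slope, self.min_sleep,
               self.hours_to_sld_rested, self.max_awake) <= 0:
            raise ValueError("all tiredness parameters must be positive")
        if abs(self.slope - self.threshold_tl / self.hours_to_sld_rested) > 1e-12:
            raise ValueError(
                "slope must equal threshold_tl / hours_to_sld_rested "
                f"({self.threshold_tl}/{self.hours_to_sld_rested})"
            )


@dataclass(frozen=True)
class DayUnit:
    """A new-day sleep plus the naps credited to it."""

    new_day_sleep: SleepEpisode
    credited_naps: tuple[SleepEpisode, ...] = ()

    @property
    def gamma(self) -> int:
        """Effective sleep minutes: own duration plus credited naps."""
        return self.new_day_sleep.duration + sum(
            n.duration for n in self.credited_naps
        )


@dataclass(frozen=True)
class TirednessSegment:
    """One linear TL segment, from a wake to the next new-day sleep."""

    wake_time: int
    segment_end: float
    intercept: float
    slope: float
    sld_onset: float | None
    gamma: int

    def tl_at(self, t: float) -> float:
        return self.intercept + self.slope * (t - self.wake_time)


@dataclass(frozen=True)
class TirednessTrajectory:
    subject_id: str
    segments: tuple[TirednessSegment, ...]
    asleep_intervals: tuple[tuple[int, int], ...]
    exclusion_windows: tuple[tuple[float, float], ...]
    horizon: float


def classify_episodes(schedule: SleepSchedule) -> list[DayUnit]:
    """Split a schedule into day units.

    An episode is a new-day sleep iff (a) it spans a calendar-day boundary,
    or (b) it starts on or after the day following the previous new-day
    sleep's end date; the first episode always starts a unit.  Every other
    episode is a nap credited to the *next* new-day sleep; naps after the
    final new-day sleep are discarded (logged).
    """
    units: list[DayUnit] = []
    pending: list[SleepEpisode] = []
    prev_end_date: int | None = None
    for i, ep in enumerate(schedule.episodes):
        spans_midnight = day_index(ep.start) < day_index(ep.end)
        after_rest_day = (
            prev_end_date is not None and day_index(ep.start) >= prev_end_date + 1
        )
        if i == 0 or spans_midnight or after_rest_day:
            units.append(DayUnit(ep, tuple(pending)))
            pending = []
            prev_end_date = day_index(ep.end)
        else:
            pending.append(ep)
    if pending:
        logger.info(
            "subject %s: discarded %d trailing naps after the last new-day sleep",
            schedule.subject_id, len(pending),
        )
    return units


def effective_gamma(unit: DayUnit) -> int:
    """Effective sleep minutes of a day unit (new-day sleep + credited naps)."""
    return unit.gamma


def initial_tl(gamma: float, params: TirednessParams = TirednessParams()) -> float:
    """TL at wake after an effective sleep of ``gamma`` minutes:
    max(threshold_tl - gamma, 0)."""
    if gamma < 1:
        raise ValueError(f"gamma must be >= 1 minute, got {gamma}")
    return max(params.threshold_tl - gamma, 0.0)


def exclusion_windows(
    schedule: SleepSchedule, params: TirednessParams = TirednessParams()
) -> list[tuple[float, float]]:
    """Sensor-dropout windows: for each consecutive pair of episodes (naps
    reset the clock too) with a gap strictly over ``max_awake`` minutes,
    the window (prev_end + max_awake, next_start)."""
    wins: list[tuple[float, float]] = []
    eps = schedule.episodes
    for prev, nxt in zip(eps, eps[1:]):
        if nxt.start - prev.end > params.max_awake:
            wins.append((prev.end + params.max_awake, nxt.start))
    return wins


def build_trajectory(
    schedule: SleepSchedule, params: TirednessParams = TirednessParams()
) -> TirednessTrajectory:
    """Build the piecewise-linear trajectory of one subject.

    One segment per day unit: the segment starts at the new-day sleep's
    end and runs to the next new-day sleep's start (the last segment runs
    to the horizon, last episode end + ``max_awake``).  The deprivation
    onset, when the segment is long enough to reach it, lies
    ``(threshold_tl - intercept)/slope`` minutes after wake.
    """
    units = classify_episodes(schedule)
    if not units:
        return TirednessTrajectory(schedule.subject_id, (), (), (), 0.0)
    horizon = float(schedule.episodes[-1].end + params.max_awake)
    segments: list[TirednessSegment] = []
    for i, unit in enumerate(units):
        wake = unit.new_day_sleep.end
        seg_end = (
            float(units[i + 1].new_day_sleep.start)
            if i + 1 < len(units)
            else horizon
        )
        b = initial_tl(unit.gamma, params)
        onset = wake + (params.threshold_tl - b) / params.slope
        segments.append(
            TirednessSegment(
                wake_time=wake,
                segment_end=seg_end,
                intercept=b,
                slope=params.slope,
                sld_onset=onset if onset < seg_end else None,
                gamma=unit.gamma,
            )
        )
    return TirednessTrajectory(
        subject_id=schedule.subject_id,
        segments=tuple(segments),
        asleep_intervals=tuple((ep.start, ep.end) for ep in schedule.episodes),
        exclusion_windows=tuple(exclusion_windows(schedule, params)),
        horizon=horizon,
    )


def tiredness_at(traj: TirednessTrajectory, t: float) -> float | str:
    """Query the trajectory at time ``t`` (minutes since epoch).

    Returns the TL value, or one of the sentinels :data:`ASLEEP` (inside
    a recorded sleep episode), :data:`EXCLUDED` (inside an exclusion
    window or past the horizon), :data:`UNDEFINED` (before the first wake
    or empty trajectory).
    """
    if not traj.segments:
        return UNDEFINED
    for s, e in traj.asleep_intervals:
        if s <= t < e:
            return ASLEEP
    if t >= traj.horizon:
        return EXCLUDED
    for s, e in traj.exclusion_windows:
        if s <= t < e:
            return EXCLUDED
    first_wake = traj.segments[0].wake_time
    if t < first_wake:
        return UNDEFINED
    for seg in traj.segments:
        if seg.wake_time <= t < seg.segment_end:
            return seg.tl_at(t)
    return UNDEFINED


def sld_intervals(
    traj: TirednessTrajectory, params: TirednessParams = TirednessParams()
) -> list[tuple[float, float]]:
    """Sleep-deprived intervals: [sld_onset, segment_end) of every segment
    whose onset precedes its end.  TL == threshold counts as deprived."""
    return [
        (seg.sld_onset, seg.segment_end)
        for seg in traj.segments
        if seg.sld_onset is not None
    ]


def write_trajectory_csv(path, trajectories: dict[str, TirednessTrajectory]) -> None:
    """Audit export: one row per segment,
    ``subject_id,wake_time,segment_end,gamma,intercept,sld_onset``."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["subject_id", "wake_time", "segment_end", "gamma", "intercept", "sld_onset"]
        )
        for sid in sorted(trajectories):
            for seg in trajectories[sid].segments:
                w.writerow(
                    [
                        sid,
                        format_ts(seg.wake_time),
                        format_ts(seg.segment_end),
                        seg.gamma,
                        repr(seg.intercept),
                        "" if seg.sld_onset is None else format_ts(seg.sld_onset),
                    ]
                )
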