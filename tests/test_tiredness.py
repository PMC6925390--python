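"""Tiredness-model unit tests and minute-grid oracle equivalence.

The brute-force oracle accumulates the slope minute by minute over each
segment (an independent path from the closed-form evaluation) and
re-derives episode classification by literal application of the two
new-day rules.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from somnotext import (
    SleepEpisode,
    build_trajectory,
    classify_episodes,
    effective_gamma,
    exclusion_windows,
    initial_tl,
    merge_episodes,
    parse_ts,
    sld_intervals,
    tiredness_at,
)
from somnotext.tiredness import ASLEEP, EXCLUDED, UNDEFINED, DayUnit, TirednessParams

from conftest import random_schedule

D = 1440  # minutes per day


# ---------------------------------------------------------------- oracles
def oracle_new_day_flags(episodes):
    """Literal episode-by-episode application of the new-day rules:
    (a) spans a calendar-day boundary, or (b) starts on/after the day
    following the previous new-day sleep's end; first episode is new-day."""
    flags = []
    last_nd_end = None
    for i, ep in enumerate(episodes):
        a = ep.start // D < ep.end // D
        b = last_nd_end is not None and ep.start // D >= last_nd_end // D + 1
        flag = i == 0 or a or b
        flags.append(flag)
        if flag:
            last_nd_end = ep.end
    return flags


def minute_grid_tl(traj):
    """Accumulate slope per minute over each segment; returns
    {minute: tl} for integer minutes in all segments."""
    out = {}
    for seg in traj.segments:
        tl = seg.intercept
        for t in range(seg.wake_time, int(math.ceil(seg.segment_end))):
            out[t] = tl
            tl += seg.slope
    return out


def deprived_minutes_from_intervals(traj, params):
    mins = set()
    for s, e in sld_intervals(traj, params):
        mins.update(range(int(math.ceil(s)), int(math.ceil(e))))
    return mins


# ------------------------------------------------------- episode classing
class TestClassifyEpisodes:
    def test_worked_example_units_and_nap_credit(self, fig1_schedule):
        units = classify_episodes(fig1_schedule)
        assert [u.gamma for u in units] == [420, 240, 330]
        assert len(units[2].credited_naps) == 1
        assert units[2].credited_naps[0].duration == 90

    def test_short_midnight_spanning_episode_is_new_day(self):
        sched = merge_episodes("s", [(parse_ts("2015-10-05T23:30"), parse_ts("2015-10-06T00:10"))])
        units = classify_episodes(sched)
        assert len(units) == 1
        assert units[0].gamma == 40

    def test_empty_schedule(self):
        assert classify_episodes(merge_episodes("s", [])) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_rule_oracle_on_random_schedules(self, seed):
        rng = np.random.default_rng(1000 + seed)
        sched = random_schedule(rng, max_episodes=6)
        units = classify_episodes(sched)
        flags = oracle_new_day_flags(sched.episodes)
        assert [u.new_day_sleep for u in units] == [
            ep for ep, f in zip(sched.episodes, flags) if f
        ]
        # each nap is credited to the next new-day sleep, or discarded
        credited = [n for u in units for n in u.credited_naps]
        naps = [ep for ep, f in zip(sched.episodes, flags) if not f]
        trailing = [n for n in naps if all(n.start > u.new_day_sleep.start for u in units)]
        assert credited == [n for n in naps if n not in trailing]


class TestGammaAndIntercept:
    @pytest.mark.parametrize(
        "gamma_parts,expected",
        [((420, ()), 420), ((240, ()), 240), ((240, (90,)), 330)],
    )
    def test_effective_gamma(self, gamma_parts, expected):
        dur, naps = gamma_parts
        unit = DayUnit(
            SleepEpisode("s", 0, dur),
            tuple(SleepEpisode("s", 10_000 + i, 10_000 + i + n) for i, n in enumerate(naps)),
        )
        assert effective_gamma(unit) == expected

    @pytest.mark.parametrize("gamma,expected", [(420, 0.0), (240, 120.0), (360, 0.0), (1, 359.0)])
    def test_initial_tl(self, gamma, expected):
        assert initial_tl(gamma) == expected

    def test_initial_tl_rejects_sub_minute_sleep(self):
        with pytest.raises(ValueError):
            initial_tl(0)

    @settings(max_examples=100, derandomize=True)
    @given(hst.integers(1, 2000))
    def test_initial_tl_bounded(self, gamma):
        b = initial_tl(gamma)
        assert 0.0 <= b <= 360.0
        if gamma >= 360:
            assert b == 0.0


# ------------------------------------------------------------ trajectories
class TestTrajectory:
    def test_worked_example_segments(self, fig1_trajectory):
        seg1, seg2, seg3 = fig1_trajectory.segments
        assert (seg1.intercept, seg2.intercept) == (0.0, 120.0)
        assert seg1.sld_onset == parse_ts("2015-10-05T23:00")
        assert seg2.sld_onset == parse_ts("2015-10-06T14:40")
        assert all(s.slope == 3 / 8 for s in fig1_trajectory.segments)

    def test_query_semantics(self, fig1_trajectory):
        at = lambda s: tiredness_at(fig1_trajectory, parse_ts(s))
        assert at("2015-10-05T07:00") == 0.0  # wake instant
        assert at("2015-10-06T13:45") == ASLEEP  # inside the nap
        assert at("2015-10-05T03:00") == ASLEEP  # inside first night
        assert at("2015-10-04T20:00") == UNDEFINED  # before first wake
        assert at("2015-10-09T00:00") == EXCLUDED  # past the horizon

    def test_sld_intervals_worked_example(self, fig1_trajectory, params):
        ivs = sld_intervals(fig1_trajectory, params)
        assert ivs[0] == (parse_ts("2015-10-05T23:00"), parse_ts("2015-10-06T00:00"))

    def test_rested_short_segment_never_deprived(self, params):
        # 7-h sleep then the next new-day sleep only 10 h after wake: the
        # 16-h onset is never reached inside the segment
        sched = merge_episodes("s", [
            (parse_ts("2015-10-05T00:00"), parse_ts("2015-10-05T07:00")),
            (parse_ts("2015-10-05T17:00"), parse_ts("2015-10-06T01:00")),
        ])
        traj = build_trajectory(sched, params)
        assert traj.segments[0].sld_onset is None

    @pytest.mark.parametrize("seed", range(20))
    def test_closed_form_equals_minute_grid(self, seed, params):
        rng = np.random.default_rng(2000 + seed)
        traj = build_trajectory(random_schedule(rng), params)
        grid = minute_grid_tl(traj)
        for seg in traj.segments:
            for t in range(seg.wake_time, int(math.ceil(seg.segment_end))):
                assert abs(seg.tl_at(t) - grid[t]) < 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_tiredness_at_agrees_with_grid(self, seed, params):
        rng = np.random.default_rng(3000 + seed)
        sched = random_schedule(rng)
        traj = build_trajectory(sched, params)
        grid = minute_grid_tl(traj)
        asleep = set()
        for ep in sched.episodes:
            asleep.update(range(ep.start, ep.end))
        excluded = set()
        for a, b in zip(sched.episodes, sched.episodes[1:]):
            if b.start - a.end > params.max_awake:
                excluded.update(range(a.end + params.max_awake, b.start))
        lo = sched.episodes[0].start - 100
        hi = int(traj.horizon) + 100
        for t in map(int, rng.integers(lo, hi, size=300)):
            got = tiredness_at(traj, t)
            if t in asleep:
                assert got == ASLEEP
            elif t >= traj.horizon or t in excluded:
                assert got == EXCLUDED
            elif t < traj.segments[0].wake_time:
                assert got == UNDEFINED
            else:
                assert got == grid[t]

    @pytest.mark.parametrize("seed", range(20))
    def test_sld_intervals_equal_grid_threshold_set(self, seed, params):
        rng = np.random.default_rng(4000 + seed)
        traj = build_trajectory(random_schedule(rng), params)
        grid = minute_grid_tl(traj)
        assert deprived_minutes_from_intervals(traj, params) == {
            t for t, tl in grid.items() if tl >= params.threshold_tl
        }

    @pytest.mark.parametrize("seed", range(10))
    def test_minutes_partition_after_first_wake(self, seed, params):
        """Every in-horizon minute after first wake is exactly one of:
        asleep, excluded, or carries a TL value."""
        rng = np.random.default_rng(5000 + seed)
        traj = build_trajectory(random_schedule(rng), params)
        first_wake = traj.segments[0].wake_time
        for t in range(first_wake, int(traj.horizon), 7):
            q = tiredness_at(traj, t)
            assert q != UNDEFINED


class TestExclusionWindows:
    def test_thirty_hour_gap(self):
        sched = merge_episodes("s", [
            (parse_ts("2015-10-05T00:00"), parse_ts("2015-10-05T08:00")),
            (parse_ts("2015-10-06T14:00"), parse_ts("2015-10-06T20:00")),
        ])
        assert exclusion_windows(sched) == [
            (parse_ts("2015-10-06T12:00"), parse_ts("2015-10-06T14:00"))
        ]

    def test_gap_of_exactly_28_hours_is_kept(self):
        sched = merge_episodes("s", [
            (parse_ts("2015-10-05T00:00"), parse_ts("2015-10-05T08:00")),
            (parse_ts("2015-10-06T12:00"), parse_ts("2015-10-06T20:00")),
        ])
        assert exclusion_windows(sched) == []

    def test_all_short_gaps_give_no_windows(self, fig1_schedule):
        assert exclusion_windows(fig1_schedule) == []

    def test_nap_resets_the_28h_clock(self):
        # 15-min nap 20 h after wake: both surrounding gaps stay under 28 h
        sched = merge_episodes("s", [
            (parse_ts("2015-10-05T00:00"), parse_ts("2015-10-05T08:00")),
            (parse_ts("2015-10-06T04:00"), parse_ts("2015-10-06T04:15")),
            (parse_ts("2015-10-07T06:00"), parse_ts("2015-10-07T12:00")),
        ])
        assert exclusion_windows(sched) == []


def test_params_validate_slope_consistency():
    with pytest.raises(ValueError):
        TirednessParams(slope=0.5)
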