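"""Build a tiredness trajectory from a few sleep episodes.

A student sleeps a full 7 h (00:00-07:00), then only 4 h the next night,
naps 90 min in the afternoon, and recovers with a 03:00-07:00 sleep.
Prints one line per linear segment: when the day starts, the effective
sleep gamma (night + credited naps), the TL intercept max(360-gamma, 0),
and the deprivation onset (TL reaching 360), if the day lasts that long.
"""

from somnotext import build_trajectory, format_ts, merge_episodes, parse_ts

episodes = [
    ("2015-10-05T00:00", "2015-10-05T07:00"),   # full night
    ("2015-10-06T00:00", "2015-10-06T04:00"),   # short night
    ("2015-10-06T13:30", "2015-10-06T15:00"),   # nap -> credited to next day
    ("2015-10-07T03:00", "2015-10-07T07:00"),   # recovery new-day sleep
]
schedule = merge_episodes("student", [(parse_ts(a), parse_ts(b)) for a, b in episodes])
traj = build_trajectory(schedule)

for seg in traj.segments:
    onset = "never" if seg.sld_onset is None else format_ts(seg.sld_onset)
    print(
        f"wake {format_ts(seg.wake_time)}  gamma {seg.gamma:4d} min  "
        f"intercept {seg.intercept:5.1f}  deprived from {onset}"
    )
print(
    "\nTL rises 3/8 per awake minute; 'deprived from' marks TL >= 360 "
    "(16 h after wake when fully rested, earlier after short sleep)."
)
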