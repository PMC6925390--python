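"""Label posts as sleep-deprived or sleep-sufficient.

Uses the bundled worked-example fixtures (one student's sleep schedule
and nine timestamped posts) and prints each post's tiredness level and
label, or the reason it was dropped.
"""

from importlib import resources

from somnotext import build_trajectory, format_ts, label_posts, read_posts, read_sleep_csv

fixtures = resources.files("somnotext.data") / "fixtures"
schedules = read_sleep_csv(str(fixtures / "fig1_sleep.csv"))
posts = read_posts(str(fixtures / "fig1_posts.csv"))
trajectories = {sid: build_trajectory(s) for sid, s in schedules.items()}

for lp in label_posts(posts, trajectories):
    when = format_ts(lp.post.timestamp)
    if lp.drop_reason == "none":
        print(f"{when}  TL {lp.tl:6.2f}  {lp.label:17s}  {lp.post.text[:40]}")
    else:
        print(f"{when}  dropped ({lp.drop_reason}): {lp.post.text[:40]}")

print(
    "\nA post is sleep_deprived when TL >= 360 at posting time; posts "
    "inside recorded sleep or sensor-gap windows carry a drop reason."
)
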