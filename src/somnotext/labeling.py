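"""Join posts to tiredness trajectories and emit binary labels.

A post is *sleep_deprived* when the author's tiredness level at posting
time is at or above the deprivation threshold, *sleep_sufficient*
otherwise.  Posts that cannot be labeled carry a drop reason instead:

- ``asleep``     — timestamp falls inside a recorded sleep episode
                   (authors asleep cannot post; indicates clock skew);
- ``excluded``   — inside a sensor-dropout exclusion window;
- ``undefined``  — before the subject's first wake;
- ``no_schedule``— the subject has no sleep data at all.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .io_ingest import Post
from .tiredness import (
    ASLEEP,
    EXCLUDED,
    UNDEFINED,
    TirednessParams,
    TirednessTrajectory,
    tiredness_at,
)

logger = logging.getLogger(__name__)

LABEL_DEPRIVED = "sleep_deprived"
LABEL_SUFFICIENT = "sleep_sufficient"
DROP_NONE = "none"
DROP_NO_SCHEDULE = "no_schedule"
DROP_REASONS = (DROP_NONE, ASLEEP, EXCLUDED, UNDEFINED, DROP_NO_SCHEDULE)


@dataclass(frozen=True)
class LabeledPost:
    """A post joined to its tiredness level; label iff not dropped."""

    post: Post
    tl: float | None
    label: str | None
    drop_reason: str = DROP_NONE

    def __post_init__(self) -> None:
        if (self.label is None) != (self.drop_reason != DROP_NONE):
            raise ValueError("label must be present exactly when drop_reason is none")


def label_posts(
    posts: list[Post],
    trajectories: dict[str, TirednessTrajectory],
    params: TirednessParams = TirednessParams(),
) -> list[LabeledPost]:
    """Label every post; input order is preserved and every post appears
    exactly once in the output (problems become drop reasons, never
    errors).  Per-label and per-drop-reason counts are logged."""
    out: list[LabeledPost] = []
    counts: Counter[str] = Counter()
    for post in posts:
        traj = trajectories.get(post.subject_id)
        if traj is None:
            out.append(LabeledPost(post, None, None, DROP_NO_SCHEDULE))
            counts[DROP_NO_SCHEDULE] += 1
            continue
        q = tiredness_at(traj, post.timestamp)
        if q in (ASLEEP, EXCLUDED, UNDEFINED):
            out.append(LabeledPost(post, None, None, q))
            counts[q] += 1
        else:
            tl = float(q)
            label = LABEL_DEPRIVED if tl >= params.threshold_tl else LABEL_SUFFICIENT
            out.append(LabeledPost(post, tl, label))
            counts[label] += 1
    logger.info(
        "labeled %d posts: %s",
        len(out),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
    )
    return out
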