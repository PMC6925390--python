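"""Readers and writers for the package's file formats.

Formats
-------
sleep CSV
    ``subject_id,start,end`` with ISO-8601 minute-precision timestamps;
    one wearable-recorded sleep episode per row.
posts
    CSV ``post_id,subject_id,timestamp,text`` or JSON-lines with the same
    keys; one timestamped micro-blog post per row.
labeled CSV
    ``post_id,subject_id,timestamp,tl,label,drop_reason`` as written by
    :func:`write_labeled_posts`; ``tl``/``label`` are empty strings when a
    post was dropped.

Overlapping (or back-to-back) sleep episodes within a subject are merged
into their union: consumer-device exports can fragment a single sleep
into adjacent rows, and merging preserves total covered minutes.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .timeutil import format_ts, parse_ts

logger = logging.getLogger(__name__)

SLEEP_COLUMNS = ["subject_id", "start", "end"]
POST_COLUMNS = ["post_id", "subject_id", "timestamp", "text"]
LABELED_COLUMNS = ["post_id", "subject_id", "timestamp", "tl", "label", "drop_reason"]


@dataclass(frozen=True)
class SleepEpisode:
    """One recorded sleep interval, half-open [start, end), minutes."""

    subject_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"sleep episode must satisfy start < end, got "
                f"[{format_ts(self.start)}, {format_ts(self.end)}) "
                f"for subject {self.subject_id!r}"
            )

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SleepSchedule:
    """Chronologically ordered, non-overlapping episodes of one subject."""

    subject_id: str
    episodes: tuple[SleepEpisode, ...]

    def __post_init__(self) -> None:
        for ep in self.episodes:
            if ep.subject_id != self.subject_id:
                raise ValueError(
                    f"episode subject {ep.subject_id!r} does not match "
                    f"schedule subject {self.subject_id!r}"
                )
        for a, b in zip(self.episodes, self.episodes[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"episodes overlap or are unsorted for subject "
                    f"{self.subject_id!r}: {format_ts(a.start)}-{format_ts(a.end)} "
                    f"then {format_ts(b.start)}-{format_ts(b.end)}"
                )


@dataclass(frozen=True)
class Post:
    """One timestamped post; text is non-empty after whitespace strip."""

    post_id: str
    subject_id: str
    timestamp: int
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"post {self.post_id!r} has empty text")


def merge_episodes(subject_id: str, intervals: Iterable[tuple[int, int]]) -> SleepSchedule:
    """Build a validated schedule, merging overlapping or touching intervals.

    Merging is idempotent and preserves the set of covered minutes.
    """
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    eps = tuple(SleepEpisode(subject_id, s, e) for s, e in merged)
    return SleepSchedule(subject_id, eps)


def read_sleep_csv(path: str | Path) -> dict[str, SleepSchedule]:
    """Read a sleep CSV into per-subject schedules.

    Episodes are grouped by subject, sorted, and overlapping/touching
    episodes merged.  Malformed timestamps and non-positive durations
    raise with the offending row number (1-based, excluding header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SLEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sleep CSV {path} missing columns {missing}")
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start = parse_ts(row.start)
            end = parse_ts(row.end)
        except ValueError as exc:
            raise ValueError(f"row {i}: malformed timestamp ({exc})") from None
        if end <= start:
            raise ValueError(
                f"row {i}: episode end {row.end} is not after start {row.start}"
            )
        by_subject.setdefault(str(row.subject_id), []).append((start, end))
    return {
        sid: merge_episodes(sid, ivs) for sid, ivs in sorted(by_subject.items())
    }


def _post_from_record(rec: dict, where: str) -> Post | None:
    missing = [k for k in POST_COLUMNS if k not in rec]
    if missing:
        raise ValueError(f"{where}: missing fields {missing}")
    text = str(rec["text"])
    if not text.strip():
        return None
    try:
        ts = parse_ts(str(rec["timestamp"]))
    except ValueError as exc:
        raise ValueError(f"{where}: malformed timestamp ({exc})") from None
    return Post(str(rec["post_id"]), str(rec["subject_id"]), ts, text)


def read_posts(path: str | Path) -> list[Post]:
    """Read posts from CSV or JSON-lines (by extension: .jsonl/.ndjson/.json).

    Returns posts sorted by (subject_id, timestamp).  Rows with empty text
    are skipped with a logged count; duplicate post ids raise.
    """
    path = Path(path)
    records: list[dict] = []
    if path.suffix.lower() in {".jsonl", ".ndjson", ".json"}:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"line {i}: invalid JSON ({exc})") from None
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = df.to_dict(orient="records")

    posts: list[Post] = []
    seen: set[str] = set()
    n_empty = 0
    for i, rec in enumerate(records, start=1):
        post = _post_from_record(rec, f"row {i}")
        if post is None:
            n_empty += 1
            continue
        if post.post_id in seen:
            raise ValueError(f"row {i}: duplicate post_id {post.post_id!r}")
        seen.add(post.post_id)
        posts.append(post)
    if n_empty:
        logger.warning("skipped %d posts with empty text", n_empty)
    posts.sort(key=lambda p: (p.subject_id, p.timestamp, p.post_id))
    return posts


def write_labeled_posts(path: str | Path, rows: Iterable) -> None:
    """Write labeled posts to CSV (see :mod:`somnotext.labeling` for the row
    type).  Dropped rows get empty ``tl`` and ``label`` fields; ``tl`` floats
    are written with ``repr`` so re-reading is bit-exact."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(LABELED_COLUMNS)
        for lp in rows:
            dropped = lp.drop_reason != "none"
            w.writerow(
                [
                    lp.post.post_id,
                    lp.post.subject_id,
                    format_ts(lp.post.timestamp),
                    "" if dropped else repr(float(lp.tl)),
                    "" if dropped else lp.label,
                    "" if lp.drop_reason == "none" else lp.drop_reason,
                ]
            )


def read_labeled_posts(path: str | Path) -> pd.DataFrame:
    """Read a labeled-posts CSV back into a typed DataFrame.

    ``tl`` becomes float (NaN for dropped rows), ``label`` None for dropped
    rows, ``drop_reason`` the string "none" for kept rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LABELED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"labeled CSV {path} missing columns {missing}")
    df = df.copy()
    df["tl"] = [float(v) if v != "" else float("nan") for v in df["tl"]]
    df["label"] = [v if v != "" else None for v in df["label"]]
    df["drop_reason"] = [v if v != "" else "none" for v in df["drop_reason"]]
    return df
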