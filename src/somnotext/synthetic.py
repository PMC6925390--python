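"""Synthetic sleep schedules and state-dependent post streams.

The generator emulates the study conditions end to end: nightly sleeps
whose durations straddle the 6-h deprivation threshold (truncated normal
around 6.5 h), occasional afternoon naps, occasional skipped nights that
force >28-h sensor gaps, and posts placed uniformly over awake minutes.
Post text is drawn from state-conditional unigram distributions over a
Zipf-weighted synthetic vocabulary:

    P_dep = (1 - eps) * P_suff + eps * Q

where ``Q`` is ``P_suff`` renormalized on a random reduced vocabulary of
fraction ``deprived_vocab_fraction`` — deprived authors "use fewer
words" — and ``eps`` (``effect_size``) dials the text signal from none
(eps=0, identical distributions) to strong.  A small set of
lexicon-scored sentiment words is mixed in, with the positive/negative
balance shifted by ``sentiment_shift`` when deprived.

Ground-truth states come from the same tiredness model the pipeline
uses, so pipeline labels must equal generator truth for every
non-dropped post; independence of the model itself is established by the
minute-grid oracle tests, not here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from .io_ingest import Post, SleepSchedule, merge_episodes
from .tiredness import (
    EXCLUDED,
    TirednessParams,
    TirednessTrajectory,
    build_trajectory,
    tiredness_at,
)
from .timeutil import MIN_PER_DAY, format_ts, to_minutes

logger = logging.getLogger(__name__)

TRUTH_DEPRIVED = "deprived"
TRUTH_SUFFICIENT = "sufficient"
TRUTH_EXCLUDED = "excluded"

#: sentiment words mixed into generated posts; all appear in the bundled lexicon
POS_WORDS = ("good", "great", "happy", "love", "awesome",
             "nice", "fun", "best", "amazing", "excited")
NEG_WORDS = ("bad", "sad", "tired", "awful", "terrible",
             "hate", "worst", "sick", "angry", "bored")

_DAY0 = to_minutes(datetime(2015, 10, 5))  # schedule origin (arbitrary Monday)


@dataclass(frozen=True)
class WorldConfig:
    """Synthetic-world parameters (minutes unless noted).

    ``mean_sleep``/``sd_sleep`` put nightly durations astride the 360-min
    deprivation threshold; ``gap_prob`` is the per-night chance of a
    skipped night (no two in a row, first and last nights always slept),
    which forces a >28-h awake gap; ``effect_size`` is the unigram
    mixture weight eps; ``deprived_vocab_fraction`` the share of the
    vocabulary deprived posts draw from; ``sentiment_shift`` the change
    in the probability that a mixed-in sentiment word is positive when
    deprived.
    """

    n_subjects: int = 20
    n_days: int = 14
    mean_sleep: float = 390.0
    sd_sleep: float = 90.0
    min_sleep_gen: int = 60
    max_sleep_gen: int = 720
    nap_prob: float = 0.2
    nap_len: int = 90
    gap_prob: float = 0.05
    posts_per_day: float = 4.0
    vocab_size: int = 500
    effect_size: float = 0.4
    deprived_vocab_fraction: float = 0.6
    sentiment_shift: float = -0.2
    sentiment_word_prob: float = 0.3
    mean_post_len: float = 8.0
    n_background_sentences: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nap_prob", "gap_prob", "effect_size",
                     "deprived_vocab_fraction", "sentiment_word_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_subjects, self.n_days, self.vocab_size) < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    schedules: dict[str, SleepSchedule]
    trajectories: dict[str, TirednessTrajectory]
    posts: list[Post]
    truth: dict[str, str]
    corpus: list[list[str]]
    reduced_vocab: np.ndarray = field(repr=False, default=None)


def _truncated_normal(rng, mean, sd, lo, hi) -> int:
    """Rejection-sampled normal duration, integer minutes."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return int(round(x))
    return int(np.clip(mean, lo, hi))


def _unigram_distributions(config: WorldConfig, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P_suff, P_dep, reduced-vocab ids) over the synthetic vocabulary."""
    V = config.vocab_size
    base = 1.0 / np.arange(1, V + 1)  # Zipf weights
    p_suff = base / base.sum()
    n_red = max(1, int(round(config.deprived_vocab_fraction * V)))
    reduced = np.sort(rng.permutation(V)[:n_red])
    q = np.zeros(V)
    q[reduced] = p_suff[reduced]
    q /= q.sum()
    p_dep = (1.0 - config.effect_size) * p_suff + config.effect_size * q
    return p_suff, p_dep, reduced


def _night_plan(config: WorldConfig, rng) -> list[bool]:
    """Which nights are slept: first and last always, no two skips in a row."""
    slept = [True] * config.n_days
    prev_skipped = False
    for d in range(1, config.n_days - 1):
        if not prev_skipped and rng.random() < config.gap_prob:
            slept[d] = False
            prev_skipped = True
        else:
            prev_skipped = False
    return slept


def _subject_schedule(sid: str, config: WorldConfig, rng) -> SleepSchedule:
    intervals: list[tuple[int, int]] = []
    slept = _night_plan(config, rng)
    for d in range(config.n_days):
        if slept[d]:
            start = _DAY0 + d * MIN_PER_DAY + 23 * 60 + int(rng.integers(0, 60))
            dur = _truncated_normal(
                rng, config.mean_sleep, config.sd_sleep,
                config.min_sleep_gen, config.max_sleep_gen,
            )
            intervals.append((start, start + dur))
        # an afternoon nap the following day; skipped after a skipped night
        # so that forced gaps really exceed 28 h (any sleep resets the clock)
        if slept[d] and d + 1 < config.n_days and rng.random() < config.nap_prob:
            nap_start = _DAY0 + (d + 1) * MIN_PER_DAY + 13 * 60 + int(rng.integers(0, 120))
            intervals.append((nap_start, nap_start + config.nap_len))
    return merge_episodes(sid, intervals)


def _post_tokens(rng, p: np.ndarray, config: WorldConfig, deprived: bool) -> list[str]:
    length = int(rng.poisson(config.mean_post_len)) + 1
    ids = rng.choice(config.vocab_size, size=length, p=p)
    toks = [f"w{i:03d}" for i in ids]
    if rng.random() < config.sentiment_word_prob:
        p_pos = 0.5 + (config.sentiment_shift if deprived else 0.0)
        p_pos = float(np.clip(p_pos, 0.0, 1.0))
        pool = POS_WORDS if rng.random() < p_pos else NEG_WORDS
        toks.append(pool[int(rng.integers(0, len(pool)))])
    return toks


def generate_world(
    config: WorldConfig = WorldConfig(),
    params: TirednessParams = TirednessParams(),
) -> SyntheticWorld:
    """Generate schedules, posts, ground-truth states, and a training
    corpus; byte-identical for a fixed config (single seeded generator
    stream per subject)."""
    root = np.random.SeedSequence(config.seed)
    world_rng = np.random.default_rng(root.spawn(1)[0])
    p_suff, p_dep, reduced = _unigram_distributions(config, world_rng)

    schedules: dict[str, SleepSchedule] = {}
    trajectories: dict[str, TirednessTrajectory] = {}
    posts: list[Post] = []
    truth: dict[str, str] = {}
    corpus: list[list[str]] = []
    subject_seeds = root.spawn(config.n_subjects + 1)[1:]

    for si in range(config.n_subjects):
        sid = f"s{si:03d}"
        rng = np.random.default_rng(subject_seeds[si])
        schedule = _subject_schedule(sid, config, rng)
        traj = build_trajectory(schedule, params)
        schedules[sid] = schedule
        trajectories[sid] = traj

        first_wake = traj.segments[0].wake_time
        domain_end = schedule.episodes[-1].start
        awake = np.ones(domain_end - first_wake, dtype=bool)
        for s, e in traj.asleep_intervals:
            s, e = max(s, first_wake), min(e, domain_end)
            if e > s:
                awake[s - first_wake : e - first_wake] = False
        awake_minutes = np.flatnonzero(awake) + first_wake
        n_posts = int(rng.poisson(config.posts_per_day * len(awake) / MIN_PER_DAY))
        times = np.sort(rng.choice(awake_minutes, size=n_posts, replace=True))

        for k, t in enumerate(times):
            q = tiredness_at(traj, int(t))
            if q == EXCLUDED:
                state = TRUTH_EXCLUDED
            else:
                state = TRUTH_DEPRIVED if float(q) >= params.threshold_tl else TRUTH_SUFFICIENT
            deprived = state == TRUTH_DEPRIVED
            toks = _post_tokens(rng, p_dep if deprived else p_suff, config, deprived)
            pid = f"{sid}-p{k:05d}"
            posts.append(Post(pid, sid, int(t), " ".join(toks)))
            truth[pid] = state
            corpus.append(toks)

    for _ in range(config.n_background_sentences):
        length = int(world_rng.poisson(15)) + 5
        ids = world_rng.choice(config.vocab_size, size=length, p=p_suff)
        toks = [f"w{i:03d}" for i in ids]
        if world_rng.random() < config.sentiment_word_prob:
            pool = POS_WORDS if world_rng.random() < 0.5 else NEG_WORDS
            toks.append(pool[int(world_rng.integers(0, len(pool)))])
        corpus.append(toks)

    posts.sort(key=lambda p: (p.subject_id, p.timestamp, p.post_id))
    n_by_state = {s: sum(1 for v in truth.values() if v == s)
                  for s in (TRUTH_DEPRIVED, TRUTH_SUFFICIENT, TRUTH_EXCLUDED)}
    logger.info("generated world: %d posts (%s)", len(posts),
                ", ".join(f"{k}={v}" for k, v in n_by_state.items()))
    return SyntheticWorld(
        config=config,
        schedules=schedules,
        trajectories=trajectories,
        posts=posts,
        truth=truth,
        corpus=corpus,
        reduced_vocab=reduced,
    )


def world_to_files(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write sleep.csv, posts.csv, truth.csv and corpus.txt in the
    package's standard formats; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sleep": out / "sleep.csv",
        "posts": out / "posts.csv",
        "truth": out / "truth.csv",
        "corpus": out / "corpus.txt",
    }
    import csv

    with open(paths["sleep"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "start", "end"])
        for sid in sorted(world.schedules):
            for ep in world.schedules[sid].episodes:
                w.writerow([sid, format_ts(ep.start), format_ts(ep.end)])
    with open(paths["posts"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["post_id", "subject_id", "timestamp", "text"])
        for p in world.posts:
            w.writerow([p.post_id, p.subject_id, format_ts(p.timestamp), p.text])
    with open(paths["truth"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["post_id", "truth_state"])
        for p in world.posts:
            w.writerow([p.post_id, world.truth[p.post_id]])
    with open(paths["corpus"], "w", encoding="utf-8") as fh:
        for sent in world.corpus:
            fh.write(" ".join(sent) + "\n")
    return paths
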