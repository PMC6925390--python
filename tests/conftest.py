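import numpy as np
import pytest
from importlib import resources

from somnotext import (
    TirednessParams,
    build_trajectory,
    merge_episodes,
    read_posts,
    read_sleep_csv,
)


def fixture_path(name: str) -> str:
    return str(resources.files("somnotext.data").joinpath(f"fixtures/{name}"))


@pytest.fixture(scope="session")
def params() -> TirednessParams:
    return TirednessParams()


@pytest.fixture(scope="session")
def fig1_schedule():
    """The worked-example schedule: full 7-h night, 4-h night, afternoon
    nap, then a 4-h new-day sleep."""
    return read_sleep_csv(fixture_path("fig1_sleep.csv"))["student"]


@pytest.fixture(scope="session")
def fig1_trajectory(fig1_schedule, params):
    return build_trajectory(fig1_schedule, params)


@pytest.fixture(scope="session")
def fig1_posts():
    return read_posts(fixture_path("fig1_posts.csv"))


def random_schedule(rng: np.random.Generator, sid: str = "r", max_episodes: int = 8):
    """Random plausible schedule: 1..max episodes, 15 min - 10 h long,
    separated by 30 min - 50 h awake gaps (long gaps exercise the 28-h
    exclusion rule; short episodes exercise nap crediting)."""
    n = int(rng.integers(1, max_episodes + 1))
    t = int(rng.integers(0, 1440))
    intervals = []
    for _ in range(n):
        dur = int(rng.integers(15, 600))
        intervals.append((t, t + dur))
        t = t + dur + int(rng.integers(30, 3000))
    return merge_episodes(sid, intervals)
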