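"""Shared fixtures: hand-built minute frames and small simulated cohorts."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from stepurge import SimulationConfig, simulate_cohort

DAY = datetime(2016, 5, 2)


def make_minutes(pid="P001", day=DAY, present=None, steps=None,
                 device=None):
    """Build a one-day minutes frame from per-minute-of-day dicts/sets.

    ``present``: iterable of minutes-of-day that have a record with HR
    present; ``steps``: dict minute-of-day -> steps (minutes listed only in
    ``steps`` get a record with HR present too unless in ``absent_hr``).
    """
    present = set(present or [])
    steps = dict(steps or {})
    minutes = sorted(present | set(steps))
    df = pd.DataFrame({
        "participant_id": pid,
        "timestamp": [day + timedelta(minutes=m) for m in minutes],
        "steps": [int(steps.get(m, 0)) for m in minutes],
        "hr_present": [m in present for m in minutes],
    })
    if device is not None:
        df["device_intensity"] = pd.array(
            [device.get(m) for m in minutes], dtype="Int64")
    return df


def full_wear_day(pid="P001", day=DAY, steps=None):
    """A day with HR present for every minute 00:00-24:00."""
    return make_minutes(pid, day, present=range(1440), steps=steps)


def random_day(rng, pid="P001", day=DAY):
    """A random day: each minute independently recorded/HR-present, with
    random step counts; exercises all band and nonwear boundaries."""
    recorded = rng.random(1440) < rng.uniform(0.3, 1.0)
    hr = recorded & (rng.random(1440) < rng.uniform(0.5, 1.0))
    minutes = np.flatnonzero(recorded)
    steps = rng.integers(0, 160, minutes.size)
    # sprinkle exact boundary cadences
    for val in (59, 60, 99, 100, 129, 130):
        if minutes.size:
            steps[rng.integers(0, minutes.size)] = val
    return pd.DataFrame({
        "participant_id": pid,
        "timestamp": [day + timedelta(minutes=int(m)) for m in minutes],
        "steps": steps,
        "hr_present": hr[minutes],
    })


@pytest.fixture(scope="session")
def small_cohort():
    """8 participants x 4 weeks, default stochastic structure."""
    cfg = SimulationConfig(n_participants=8, n_weeks=4, seed=42,
                           p_short=0.0, p_partial=0.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = SimulationConfig(n_participants=4, n_weeks=2, seed=7,
                           p_short=0.0, p_partial=0.0)
    return simulate_cohort(cfg)
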