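"""Nonwear detection and day/week/participant validity.

The device is not worn overnight, so wear is assessed only inside a daytime
window (10:00-22:00 by default).  A nonwear period is a maximal run of at
least ``nonwear_gap_min`` consecutive in-window minutes with no heart-rate
sample; a minute with no data row at all counts as missing heart rate.  A
day is excluded when it accumulates too many nonwear periods and/or too
little wear time (the default logic requires both, mirroring the protocol's
conjunction; ``either`` is available).  Weeks are consecutive 7-day blocks
anchored at each participant's first recorded date and are valid with >=4
valid days; participants need a recorded span of >= ``min_weeks`` weeks.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import WearConfig


@dataclass
class DayWear:
    """Wear assessment for one participant-day."""

    participant_id: str
    date: _date
    wear_minutes: int
    nonwear_periods: int
    valid: bool


def _single_day(minutes: pd.DataFrame) -> None:
    if minutes.empty:
        return
    if minutes["participant_id"].nunique() > 1:
        raise ValueError("records span multiple participants")
    if minutes["timestamp"].dt.normalize().nunique() > 1:
        raise ValueError("records span multiple days")


def _window_presence(minutes: pd.DataFrame, cfg: WearConfig) -> np.ndarray:
    """Boolean heart-rate presence per window minute (index 0 = window_start)."""
    present = np.zeros(cfg.window_length, dtype=bool)
    if minutes.empty:
        return present
    mod = (minutes["timestamp"].dt.hour * 60
           + minutes["timestamp"].dt.minute).to_numpy()
    hr = minutes["hr_present"].to_numpy(dtype=bool)
    sel = (mod >= cfg.window_start) & (mod < cfg.window_end) & hr
    present[mod[sel] - cfg.window_start] = True
    return present


def find_nonwear_periods(minutes: pd.DataFrame,
                         cfg: Optional[WearConfig] = None,
                         ) -> List[Tuple[int, int]]:
    """Maximal in-window runs of HR-missing minutes of qualifying length.

    Returns disjoint, sorted half-open intervals as minutes after midnight,
    clipped to the assessment window.  Records must belong to a single
    participant-day; an empty frame yields one full-window period.
    """
    cfg = cfg or WearConfig()
    _single_day(minutes)
    present = _window_presence(minutes, cfg)
    missing = ~present
    # run-length encode the missing mask
    boundaries = np.flatnonzero(np.diff(missing.astype(np.int8))) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [missing.size]))
    out = []
    for s, e in zip(starts, ends):
        if missing[s] and e - s >= cfg.nonwear_gap_min:
            out.append((cfg.window_start + int(s), cfg.window_start + int(e)))
    return out


def classify_day(minutes: pd.DataFrame, cfg: Optional[WearConfig] = None,
                 participant_id: Optional[str] = None,
                 date: Optional[_date] = None) -> DayWear:
    """Apply the day-level exclusion rule to one participant-day.

    Under ``both`` (the default) a day is excluded only when it has
    >= ``max_nonwear_periods`` nonwear periods AND wear below
    ``min_wear_min``; under ``either`` one condition suffices.
    """
    cfg = cfg or WearConfig()
    _single_day(minutes)
    if minutes.empty:
        if participant_id is None or date is None:
            raise ValueError("participant_id and date required for an empty day")
    else:
        participant_id = str(minutes["participant_id"].iloc[0])
        date = minutes["timestamp"].iloc[0].date()
    wear = int(_window_presence(minutes, cfg).sum())
    periods = len(find_nonwear_periods(minutes, cfg))
    many_periods = periods >= cfg.max_nonwear_periods
    low_wear = wear < cfg.min_wear_min
    if cfg.exclusion_logic == "both":
        excluded = many_periods and low_wear
    else:
        excluded = many_periods or low_wear
    return DayWear(participant_id=participant_id, date=date,
                   wear_minutes=wear, nonwear_periods=periods,
                   valid=not excluded)


def classify_days(minutes: pd.DataFrame,
                  cfg: Optional[WearConfig] = None) -> pd.DataFrame:
    """Vectorized ``classify_day`` over a whole cohort.

    Returns one row per (participant, date) present in ``minutes`` with
    columns participant_id, date, wear_minutes, nonwear_periods, valid.
    """
    cfg = cfg or WearConfig()
    if minutes.empty:
        return pd.DataFrame(columns=["participant_id", "date", "wear_minutes",
                                     "nonwear_periods", "valid"])
    df = minutes[["participant_id", "timestamp", "hr_present"]].copy()
    df["date"] = df["timestamp"].dt.normalize()
    mod = df["timestamp"].dt.hour * 60 + df["timestamp"].dt.minute
    in_win = (mod >= cfg.window_start) & (mod < cfg.window_end)
    win = df[in_win & df["hr_present"]]

    # wear minutes per day
    wear = (win.groupby(["participant_id", "date"], sort=True)
            .size().rename("wear_minutes"))

    # nonwear periods per day: gaps between consecutive present minutes
    rows = []
    for (pid, day), grp in win.groupby(["participant_id", "date"], sort=True):
        mods = np.sort((grp["timestamp"].dt.hour * 60
                        + grp["timestamp"].dt.minute).to_numpy())
        edges = np.concatenate(([cfg.window_start - 1], mods, [cfg.window_end]))
        gap_lengths = np.diff(edges) - 1
        rows.append((pid, day, int((gap_lengths >= cfg.nonwear_gap_min).sum())))
    periods = pd.DataFrame(rows, columns=["participant_id", "date",
                                          "nonwear_periods"])

    days = (df[["participant_id", "date"]].drop_duplicates()
            .sort_values(["participant_id", "date"], kind="stable"))
    days = days.merge(wear.reset_index(), how="left").merge(periods, how="left")
    days["wear_minutes"] = days["wear_minutes"].fillna(0).astype(int)
    # a day with zero in-window presence is one full-window nonwear period
    empty_fill = 1 if cfg.window_length >= cfg.nonwear_gap_min else 0
    days["nonwear_periods"] = days["nonwear_periods"].fillna(empty_fill).astype(int)
    many = days["nonwear_periods"] >= cfg.max_nonwear_periods
    low = days["wear_minutes"] < cfg.min_wear_min
    excluded = (many & low) if cfg.exclusion_logic == "both" else (many | low)
    days["valid"] = ~excluded
    days["date"] = days["date"].dt.date
    return days.reset_index(drop=True)


def mark_weeks(day_wears: pd.DataFrame,
               cfg: Optional[WearConfig] = None) -> pd.DataFrame:
    """Assign days to consecutive 7-day blocks and flag valid weeks.

    Blocks are anchored at each participant's first recorded date.  The
    trailing block is kept and flagged ``partial`` when fewer than 7
    calendar days of it fall inside the participant's recorded range.
    """
    cfg = cfg or WearConfig()
    if day_wears.empty:
        return pd.DataFrame(columns=["participant_id", "week_index",
                                     "week_start", "n_days_recorded",
                                     "n_valid_days", "valid_week", "partial"])
    out = []
    for pid, grp in day_wears.groupby("participant_id", sort=True):
        dates = pd.to_datetime(grp["date"])
        anchor = dates.min()
        span_days = (dates.max() - anchor).days + 1
        week_of_day = ((dates - anchor).dt.days // 7).to_numpy()
        n_weeks = int(week_of_day.max()) + 1
        valid = grp["valid"].to_numpy(dtype=bool)
        for w in range(n_weeks):
            mask = week_of_day == w
            n_valid = int(valid[mask].sum())
            covered = min(span_days - 7 * w, 7)
            out.append({
                "participant_id": pid,
                "week_index": w,
                "week_start": (anchor + pd.Timedelta(days=7 * w)).date(),
                "n_days_recorded": int(mask.sum()),
                "n_valid_days": n_valid,
                "valid_week": n_valid >= cfg.min_days_per_week,
                "partial": covered < 7,
            })
    return pd.DataFrame(out)


def filter_participants(day_wears: pd.DataFrame,
                        cfg: Optional[WearConfig] = None,
                        ) -> Tuple[List[str], pd.DataFrame]:
    """Keep participants whose recorded span covers >= ``min_weeks`` weeks.

    The span is first-to-last recorded date inclusive; the requirement is a
    duration of recording, not a count of valid weeks.  Returns the retained
    ids and an exclusion log naming each dropped participant and the rule.
    """
    cfg = cfg or WearConfig()
    retained, dropped = [], []
    for pid, grp in day_wears.groupby("participant_id", sort=True):
        dates = pd.to_datetime(grp["date"])
        span = (dates.max() - dates.min()).days + 1
        if span >= cfg.min_weeks * 7:
            retained.append(pid)
        else:
            dropped.append({"participant_id": pid,
                            "rule": "insufficient weeks",
                            "detail": f"recorded span {span} days "
                                      f"< {cfg.min_weeks * 7}"})
    log = pd.DataFrame(dropped, columns=["participant_id", "rule", "detail"])
    return retained, log
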