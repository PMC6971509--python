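"""Reading and writing the minute-step, heart-rate, urge and profile CSVs.

Record collections are plain pandas DataFrames with fixed schemas:

``minutes``
    participant_id (str), timestamp (naive datetime, minute resolution),
    steps (int >= 0), hr_present (bool), device_intensity (nullable int,
    device levels 0=sedentary 1=light 2=moderate 3=vigorous).
``urges``
    participant_id, timestamp, urge (int in 1..9).
``profiles``
    participant_id, age, sex {man, woman}, race {white, nonwhite},
    education {high-school-or-less, some-college, bachelors-or-higher},
    bmi, cigarettes_per_day (>=3), ipaq_category {low, moderate, high},
    prompt_time_1..3 ('HH:MM', strictly increasing).

Timestamps are naive local civil time: the study windows (10:00-22:00,
participant prompt times) are clock-based, so no zone arithmetic belongs
here.  A missing minute row means "no data for that minute" — readers never
invent rows, and absence is interpreted downstream by the wear filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

STEPS_CEILING = 300  # physiological ceiling for one minute; warn above

SEX_LEVELS = ("man", "woman")
RACE_LEVELS = ("white", "nonwhite")
EDUCATION_LEVELS = ("high-school-or-less", "some-college", "bachelors-or-higher")
IPAQ_LEVELS = ("low", "moderate", "high")

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M"


class DataError(ValueError):
    """Malformed or invariant-violating input data."""


@dataclass
class MinutesDialect:
    """Column naming for minute-level CSVs.

    The defaults are this package's own dialect; ``fitabase()`` returns the
    header names of a Fitabase minute-steps export.  ``hr_is_bpm`` marks the
    heart-rate column as numeric samples (presence = non-empty) rather than
    a boolean presence flag.
    """

    participant_col: str = "participant_id"
    timestamp_col: str = "timestamp"
    steps_col: str = "steps"
    hr_col: Optional[str] = "hr_present"
    hr_is_bpm: bool = False
    intensity_col: Optional[str] = "device_intensity"
    timestamp_format: Optional[str] = TIMESTAMP_FORMAT

    @classmethod
    def fitabase(cls) -> "MinutesDialect":
        return cls(participant_col="Id", timestamp_col="ActivityMinute",
                   steps_col="Steps", hr_col=None, intensity_col="Intensity",
                   timestamp_format="%m/%d/%Y %I:%M:%S %p")


def _parse_timestamps(raw: pd.Series, fmt: Optional[str], path) -> pd.Series:
    parsed = pd.to_datetime(raw, format=fmt, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise DataError(f"{path}: malformed timestamp {raw[bad].iloc[0]!r} "
                        f"at row {row}")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2
        raise DataError(f"{path}: missing timestamp at row {row}")
    return parsed


def _check_duplicates(df: pd.DataFrame, keys, path) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].tolist()
        raise DataError(f"{path}: duplicate record for {tuple(first)}")


def read_minutes(path, dialect: Optional[MinutesDialect] = None,
                 hr_path=None) -> pd.DataFrame:
    """Read a minute-level step CSV into the ``minutes`` schema.

    ``hr_path`` optionally names a seconds-level heart-rate CSV
    (participant_id, timestamp, value); its samples are collapsed to
    per-minute presence, overriding any presence column in the main file.
    """
    dialect = dialect or MinutesDialect()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [dialect.participant_col, dialect.timestamp_col, dialect.steps_col]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")

    out = pd.DataFrame({
        "participant_id": raw[dialect.participant_col].astype(str),
        "timestamp": _parse_timestamps(
            raw[dialect.timestamp_col].replace("", None),
            dialect.timestamp_format, path),
    })
    steps = pd.to_numeric(raw[dialect.steps_col], errors="coerce")
    if steps.isna().any():
        row = int(np.flatnonzero(steps.isna().to_numpy())[0]) + 2
        raise DataError(f"{path}: non-numeric steps at row {row}")
    if (steps < 0).any():
        row = int(np.flatnonzero((steps < 0).to_numpy())[0]) + 2
        raise DataError(f"{path}: negative steps at row {row}")
    if (steps > STEPS_CEILING).any():
        warnings.warn(f"{path}: step counts above {STEPS_CEILING}/min present",
                      stacklevel=2)
    out["steps"] = steps.astype(np.int64)

    hr_col = dialect.hr_col
    if hr_col is not None and hr_col in raw.columns:
        col = raw[hr_col].str.strip()
        if dialect.hr_is_bpm:
            out["hr_present"] = col != ""
        else:
            truthy = col.str.lower().isin(("true", "1", "t", "yes"))
            out["hr_present"] = truthy
    else:
        out["hr_present"] = False

    if dialect.intensity_col is not None and dialect.intensity_col in raw.columns:
        lev = pd.to_numeric(raw[dialect.intensity_col].replace("", None),
                            errors="coerce").astype("Int64")
        valid = lev.dropna()
        if not valid.isin([0, 1, 2, 3]).all():
            raise DataError(f"{path}: device intensity levels must be 0-3")
        out["device_intensity"] = lev

    if hr_path is not None:
        hr = pd.read_csv(hr_path)
        hr_ts = _parse_timestamps(hr["timestamp"].astype(str), None, hr_path)
        present = set(zip(hr["participant_id"].astype(str),
                          hr_ts.dt.floor("min")))
        key = list(zip(out["participant_id"], out["timestamp"]))
        out["hr_present"] = [k in present for k in key]

    _check_duplicates(out, ["participant_id", "timestamp"], path)
    return out.sort_values(["participant_id", "timestamp"],
                           kind="stable").reset_index(drop=True)


def write_minutes(minutes: pd.DataFrame, path) -> None:
    out = minutes.copy()
    out["timestamp"] = out["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False)


def read_urges(path) -> pd.DataFrame:
    """Read urge responses; values outside the 1..9 Likert range are errors."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("participant_id", "timestamp", "urge"):
        if col not in raw.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame({
        "participant_id": raw["participant_id"].astype(str),
        "timestamp": _parse_timestamps(raw["timestamp"].replace("", None),
                                       TIMESTAMP_FORMAT, path),
    })
    urge = pd.to_numeric(raw["urge"], errors="coerce")
    bad = urge.isna() | (urge < 1) | (urge > 9) | (urge != urge.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise DataError(f"{path}: urge must be an integer in [1, 9] "
                        f"(row {row}: {raw['urge'].iloc[row - 2]!r})")
    out["urge"] = urge.astype(np.int64)
    _check_duplicates(out, ["participant_id", "timestamp"], path)
    return out.sort_values(["participant_id", "timestamp"],
                           kind="stable").reset_index(drop=True)


def write_urges(urges: pd.DataFrame, path) -> None:
    out = urges.copy()
    out["timestamp"] = out["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False)


PROFILE_COLUMNS = ["participant_id", "age", "sex", "race", "education", "bmi",
                   "cigarettes_per_day", "ipaq_category",
                   "prompt_time_1", "prompt_time_2", "prompt_time_3"]


def _prompt_minutes(value: str) -> int:
    hh, mm = str(value).split(":")
    return int(hh) * 60 + int(mm)


def read_profiles(path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PROFILE_COLUMNS if c not in raw.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame({"participant_id": raw["participant_id"].astype(str)})
    _check_duplicates(out, ["participant_id"], path)

    for col, levels in (("sex", SEX_LEVELS), ("race", RACE_LEVELS),
                        ("education", EDUCATION_LEVELS),
                        ("ipaq_category", IPAQ_LEVELS)):
        vals = raw[col].str.strip()
        bad = ~vals.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise DataError(f"{path}: unknown {col} label "
                            f"{vals[bad].iloc[0]!r} at row {row}")
        out[col] = vals

    age = pd.to_numeric(raw["age"], errors="coerce")
    if age.isna().any() or (age < 18).any():
        raise DataError(f"{path}: age must be an integer >= 18")
    out["age"] = age.astype(np.int64)

    bmi = pd.to_numeric(raw["bmi"], errors="coerce")
    if bmi.isna().any() or (bmi <= 0).any():
        raise DataError(f"{path}: bmi must be positive")
    out["bmi"] = bmi.astype(float)

    cpd = pd.to_numeric(raw["cigarettes_per_day"], errors="coerce")
    if cpd.isna().any() or (cpd < 3).any():
        raise DataError(f"{path}: cigarettes_per_day must be an integer >= 3 "
                        "(study inclusion criterion)")
    out["cigarettes_per_day"] = cpd.astype(np.int64)

    for col in ("prompt_time_1", "prompt_time_2", "prompt_time_3"):
        out[col] = raw[col].str.strip()
    t1 = out["prompt_time_1"].map(_prompt_minutes)
    t2 = out["prompt_time_2"].map(_prompt_minutes)
    t3 = out["prompt_time_3"].map(_prompt_minutes)
    if not ((t1 < t2) & (t2 < t3)).all():
        raise DataError(f"{path}: prompt times must be strictly increasing")

    return out[PROFILE_COLUMNS].sort_values(
        "participant_id", kind="stable").reset_index(drop=True)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles[PROFILE_COLUMNS].to_csv(path, index=False)
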