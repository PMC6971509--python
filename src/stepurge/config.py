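"""Configuration objects for the wear/intensity/adherence pipeline.

All thresholds default to the study protocol: nonwear is assessed in the
10:00-22:00 civil-time window, a nonwear period is >=90 consecutive minutes
without heart-rate data, a day is excluded when it has both >=2 nonwear
periods and <6 h wear, a week is valid with >=4 valid days, and participants
need >=6 weeks of recorded span.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


def _parse_civil_time(value) -> int:
    """Return minutes after midnight from 'HH:MM' or an int minute count."""
    if isinstance(value, int):
        minutes = value
    else:
        hh, mm = str(value).split(":")
        minutes = int(hh) * 60 + int(mm)
    if not 0 <= minutes < 1440:
        raise ValueError(f"time of day out of range: {value!r}")
    return minutes


def minutes_to_hhmm(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass
class WearConfig:
    """Nonwear detection and day/week/participant validity thresholds."""

    window_start: int = 600          # 10:00, minutes after midnight
    window_end: int = 1320           # 22:00 (exclusive)
    nonwear_gap_min: int = 90        # consecutive HR-missing minutes
    min_wear_min: int = 360          # 6 h wear within the window
    max_nonwear_periods: int = 2     # >= this many periods triggers the rule
    min_weeks: int = 6               # recorded span required for inclusion
    min_days_per_week: int = 4       # valid days for a valid week
    exclusion_logic: str = "both"    # "both": periods AND low wear; "either"

    def __post_init__(self) -> None:
        self.window_start = _parse_civil_time(self.window_start)
        self.window_end = _parse_civil_time(self.window_end)
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")
        for name in ("nonwear_gap_min", "min_wear_min", "max_nonwear_periods",
                     "min_weeks", "min_days_per_week"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.exclusion_logic not in ("both", "either"):
            raise ValueError("exclusion_logic must be 'both' or 'either'")

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start


@dataclass
class BandConfig:
    """Cadence thresholds (steps/minute) separating the four intensity bands.

    Band 0 is zero steps, band 1 is 1..light_threshold-1, band 2 runs up to
    mvpa_threshold-1, band 3 is everything at or above mvpa_threshold; the
    vigorous threshold is a sub-band of band 3.
    """

    light_threshold: int = 60    # band1 | band2 boundary
    mvpa_threshold: int = 100    # band2 | band3 boundary (moderate-or-faster)
    vpa_threshold: int = 130     # vigorous cadence within band 3

    def __post_init__(self) -> None:
        if not 0 < self.light_threshold < self.mvpa_threshold <= self.vpa_threshold:
            raise ValueError("band thresholds must satisfy 0 < light < mvpa <= vpa")


@dataclass
class AdherenceConfig:
    weekly_mvpa_min: int = 150
    weekly_vpa_min: int = 75
    week_fraction: float = 0.5
    daily_goal_min: int = 30
    ci_method: str = "wilson"    # or "clopper-pearson"

    def __post_init__(self) -> None:
        if not 0 < self.week_fraction <= 1:
            raise ValueError("week_fraction must be in (0, 1]")
        if self.ci_method not in ("wilson", "clopper-pearson"):
            raise ValueError("ci_method must be 'wilson' or 'clopper-pearson'")


@dataclass
class PipelineConfig:
    """Top-level run configuration; serializes to/from a YAML mapping."""

    wear: WearConfig = field(default_factory=WearConfig)
    bands: BandConfig = field(default_factory=BandConfig)
    adherence: AdherenceConfig = field(default_factory=AdherenceConfig)
    model_mode: str = "ar1-hetero"   # ar1-hetero | ar1-common | ri-only
    descriptives_unit: str = "participant"  # or "person-day"
    seed: int = 0
    simulate: bool = True            # generate a cohort instead of reading CSVs
    input_dir: Optional[str] = None  # required when simulate is False
    output_dir: str = "stepurge_out"
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if self.model_mode not in ("ar1-hetero", "ar1-common", "ri-only"):
            raise ValueError(f"unknown model_mode: {self.model_mode!r}")
        if self.descriptives_unit not in ("participant", "person-day"):
            raise ValueError(f"unknown descriptives_unit: {self.descriptives_unit!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key, sub in (("wear", WearConfig), ("bands", BandConfig),
                         ("adherence", AdherenceConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub)}
                sub_unknown = set(kwargs[key]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown config keys under {key!r}: {sorted(sub_unknown)}")
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["wear"]["window_start"] = minutes_to_hhmm(self.wear.window_start)
        out["wear"]["window_end"] = minutes_to_hhmm(self.wear.window_end)
        return out
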