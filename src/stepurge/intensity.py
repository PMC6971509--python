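"""Cadence-band classification and daily activity summaries.

Cadence (steps accumulated per minute) is the intensity surrogate: band 0
is no movement, band 1 (1-59) incidental movement to purposeful steps,
band 2 (60-99) slow-to-medium walking, band 3 (>=100) brisk walking and
faster.  Minutes at >=100 steps/min count as MVPA; minutes at >=130 count
as vigorous (VPA), a subset of MVPA.  No bout requirement applies: every
qualifying minute counts, wherever it falls in the day.  Banding covers all
recorded minutes of a day, not just the 10:00-22:00 wear-assessment window,
and a minute contributes its steps whether or not heart rate was sampled —
the wear rules exclude days, never individual minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import BandConfig
from .wear import DayWear, _single_day

BAND_LABELS = {0: "no movement", 1: "incidental to purposeful",
               2: "slow to medium walking", 3: "brisk walking and faster"}


def band_minute(steps: int, cfg: Optional[BandConfig] = None,
                ) -> Tuple[int, bool]:
    """Classify one minute's steps: returns (band 0-3, is_vpa)."""
    cfg = cfg or BandConfig()
    if steps < 0:
        raise ValueError(f"steps must be non-negative, got {steps}")
    if steps == 0:
        band = 0
    elif steps < cfg.light_threshold:
        band = 1
    elif steps < cfg.mvpa_threshold:
        band = 2
    else:
        band = 3
    return band, steps >= cfg.vpa_threshold


def band_array(steps: np.ndarray, cfg: Optional[BandConfig] = None,
               ) -> np.ndarray:
    """Vectorized band classification."""
    cfg = cfg or BandConfig()
    steps = np.asarray(steps)
    if (steps < 0).any():
        raise ValueError("steps must be non-negative")
    bands = np.zeros(steps.shape, dtype=np.int64)
    bands[steps >= 1] = 1
    bands[steps >= cfg.light_threshold] = 2
    bands[steps >= cfg.mvpa_threshold] = 3
    return bands


def summarize_day(minutes: pd.DataFrame, wear: DayWear,
                  cfg: Optional[BandConfig] = None) -> pd.Series:
    """Band counts, totals and weighted MVPA for one participant-day.

    ``weighted_mvpa_min`` counts moderate minutes once and vigorous minutes
    twice (the guideline's intensity equivalence), i.e. mvpa + vpa.
    """
    cfg = cfg or BandConfig()
    _single_day(minutes)
    steps = minutes["steps"].to_numpy() if len(minutes) else np.array([], int)
    bands = band_array(steps, cfg)
    counts = np.bincount(bands, minlength=4)
    vpa = int((steps >= cfg.vpa_threshold).sum())
    mvpa = int(counts[3])
    row = {
        "participant_id": wear.participant_id,
        "date": wear.date,
        "valid": wear.valid,
        "total_steps": int(steps.sum()),
        "minutes_band0": int(counts[0]),
        "minutes_band1": int(counts[1]),
        "minutes_band2": int(counts[2]),
        "minutes_band3": mvpa,
        "mvpa_min": mvpa,
        "vpa_min": vpa,
        "weighted_mvpa_min": mvpa + vpa,
    }
    if "device_intensity" in minutes.columns:
        lev = minutes["device_intensity"]
        row["device_mvpa_min"] = int(lev.isin([2, 3]).sum())
    return pd.Series(row)


def summarize_days(minutes: pd.DataFrame, day_wears: pd.DataFrame,
                   cfg: Optional[BandConfig] = None) -> pd.DataFrame:
    """Vectorized day summaries for a cohort, joined to wear validity.

    ``day_wears`` is the output of :func:`stepurge.wear.classify_days`;
    every (participant, date) in ``minutes`` must appear there.
    """
    cfg = cfg or BandConfig()
    if minutes.empty:
        cols = ["participant_id", "date", "valid", "total_steps",
                "minutes_band0", "minutes_band1", "minutes_band2",
                "minutes_band3", "mvpa_min", "vpa_min", "weighted_mvpa_min"]
        return pd.DataFrame(columns=cols)
    df = minutes.copy()
    df["date"] = df["timestamp"].dt.date
    df["band"] = band_array(df["steps"].to_numpy(), cfg)
    df["is_vpa"] = df["steps"] >= cfg.vpa_threshold
    g = df.groupby(["participant_id", "date"], sort=True)
    out = g.agg(total_steps=("steps", "sum"),
                vpa_min=("is_vpa", "sum")).reset_index()
    band_counts = (df.pivot_table(index=["participant_id", "date"],
                                  columns="band", values="steps",
                                  aggfunc="size", fill_value=0)
                   .reindex(columns=[0, 1, 2, 3], fill_value=0))
    band_counts.columns = [f"minutes_band{b}" for b in band_counts.columns]
    out = out.merge(band_counts.reset_index(),
                    on=["participant_id", "date"], how="left")
    out["mvpa_min"] = out["minutes_band3"]
    out["weighted_mvpa_min"] = out["mvpa_min"] + out["vpa_min"]
    if "device_intensity" in df.columns:
        dev = (df.assign(dev_mvpa=df["device_intensity"].isin([2, 3]))
               .groupby(["participant_id", "date"], sort=True)["dev_mvpa"]
               .sum().rename("device_mvpa_min").reset_index())
        out = out.merge(dev, on=["participant_id", "date"], how="left")
        out["device_mvpa_min"] = out["device_mvpa_min"].astype(int)
    wear_cols = day_wears[["participant_id", "date", "valid"]]
    merged = out.merge(wear_cols, on=["participant_id", "date"], how="left")
    if merged["valid"].isna().any():
        missing = merged.loc[merged["valid"].isna(),
                             ["participant_id", "date"]].iloc[0]
        raise ValueError("day missing from wear classification: "
                         f"{tuple(missing)}")
    merged["valid"] = merged["valid"].astype(bool)
    int_cols = ["total_steps", "vpa_min", "minutes_band0", "minutes_band1",
                "minutes_band2", "minutes_band3", "mvpa_min",
                "weighted_mvpa_min"]
    merged[int_cols] = merged[int_cols].astype(int)
    front = ["participant_id", "date", "valid"]
    return merged[front + [c for c in merged.columns if c not in front]]


@dataclass
class DeviceComparison:
    """Cadence-vs-device MVPA comparison; ``available`` is False when the
    minutes carry no device intensity column."""

    available: bool
    per_level: Optional[pd.DataFrame] = None   # steps distribution by level
    per_day: Optional[pd.DataFrame] = None     # paired daily MVPA measures
    correlation: Optional[float] = None        # Pearson r of the daily pair


def compare_device_intensity(minutes: pd.DataFrame,
                             day_wears: Optional[pd.DataFrame] = None,
                             cfg: Optional[BandConfig] = None,
                             ) -> DeviceComparison:
    """Contrast cadence-threshold MVPA with the device's intensity labels.

    Reports, per device level, the median/IQR/range of within-minute steps,
    and per participant-day the paired (cadence MVPA, device MVPA) minutes
    with their Pearson correlation.
    """
    cfg = cfg or BandConfig()
    if "device_intensity" not in minutes.columns or \
            minutes["device_intensity"].isna().all():
        return DeviceComparison(available=False)
    df = minutes.dropna(subset=["device_intensity"]).copy()
    df["device_intensity"] = df["device_intensity"].astype(int)
    per_level = (df.groupby("device_intensity")["steps"]
                 .agg(n="size", median="median",
                      q1=lambda s: s.quantile(0.25),
                      q3=lambda s: s.quantile(0.75),
                      min="min", max="max")
                 .reset_index())
    df["date"] = df["timestamp"].dt.date
    df["cadence_mvpa"] = df["steps"] >= cfg.mvpa_threshold
    df["device_mvpa"] = df["device_intensity"].isin([2, 3])
    per_day = (df.groupby(["participant_id", "date"], sort=True)
               .agg(cadence_mvpa_min=("cadence_mvpa", "sum"),
                    device_mvpa_min=("device_mvpa", "sum"))
               .reset_index())
    if day_wears is not None:
        per_day = per_day.merge(
            day_wears[["participant_id", "date", "valid"]],
            on=["participant_id", "date"], how="left")
        per_day = per_day[per_day["valid"].fillna(False).astype(bool)]
    x = per_day["cadence_mvpa_min"].to_numpy(float)
    y = per_day["device_mvpa_min"].to_numpy(float)
    corr = None
    if len(per_day) >= 2 and x.std() > 0 and y.std() > 0:
        corr = float(np.corrcoef(x, y)[0, 1])
    return DeviceComparison(available=True, per_level=per_level,
                            per_day=per_day.reset_index(drop=True),
                            correlation=corr)
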