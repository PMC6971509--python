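"""Weekly activity totals and physical-activity guideline adherence.

The guideline benchmark is >=150 min/week of moderate-to-vigorous activity
or >=75 min/week of vigorous activity.  A participant is adherent when the
benchmark is met on at least half of their valid weeks (a valid week has
>=4 valid days); participants with no valid week are non-evaluable and
leave the denominator.  Cohort prevalence carries a 95% Wilson score
interval, with percentages rounded to the nearest integer (half away from
zero) for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import AdherenceConfig


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def wilson_interval(n_meeting: int, n_total: int,
                    alpha: float = 0.05) -> Tuple[float, float]:
    """95% (by default) Wilson score interval for a binomial proportion."""
    low, high = proportion_confint(n_meeting, n_total, alpha=alpha,
                                   method="wilson")
    # the closed form gives exactly 0/1 at the boundaries
    low = 0.0 if n_meeting == 0 else float(low)
    high = 1.0 if n_meeting == n_total else float(high)
    return low, high


def clopper_pearson_interval(n_meeting: int, n_total: int,
                             alpha: float = 0.05) -> Tuple[float, float]:
    low, high = proportion_confint(n_meeting, n_total, alpha=alpha,
                                   method="beta")
    return float(np.nan_to_num(low)), float(np.nan_to_num(high, nan=1.0))


def weekly_totals(day_summaries: pd.DataFrame, week_shells: pd.DataFrame,
                  cfg: Optional[AdherenceConfig] = None) -> pd.DataFrame:
    """Sum daily MVPA/VPA over each week's *valid* days and set guideline flags.

    Invalid weeks keep their totals but their guideline flags are left null:
    the benchmark is only assessed on weeks with enough complete days.
    Every day must fall inside some week shell of its participant.
    """
    cfg = cfg or AdherenceConfig()
    weeks = week_shells.copy()
    if day_summaries.empty:
        for col in ("mvpa_min_week", "vpa_min_week", "weighted_mvpa_min_week"):
            weeks[col] = 0
        weeks["meets_mvpa_guideline"] = pd.array([None] * len(weeks),
                                                 dtype="boolean")
        weeks["meets_vpa_guideline"] = pd.array([None] * len(weeks),
                                                dtype="boolean")
        return weeks

    days = day_summaries.copy()
    days["date"] = pd.to_datetime(days["date"])
    anchors = (weeks.assign(week_start=pd.to_datetime(weeks["week_start"]))
               .groupby("participant_id")["week_start"].min())
    max_week = weeks.groupby("participant_id")["week_index"].max()
    days = days.merge(anchors.rename("anchor"), left_on="participant_id",
                      right_index=True, how="left")
    if days["anchor"].isna().any():
        pid = days.loc[days["anchor"].isna(), "participant_id"].iloc[0]
        raise ValueError(f"participant {pid!r} has days but no week shells")
    days["week_index"] = (days["date"] - days["anchor"]).dt.days // 7
    bad = (days["week_index"] < 0) | (days["week_index"]
                                      > days["participant_id"].map(max_week))
    if bad.any():
        row = days.loc[bad].iloc[0]
        raise ValueError("day not covered by any week shell: "
                         f"({row['participant_id']!r}, {row['date'].date()})")

    valid_days = days[days["valid"]]
    sums = (valid_days.groupby(["participant_id", "week_index"])
            .agg(mvpa_min_week=("mvpa_min", "sum"),
                 vpa_min_week=("vpa_min", "sum"),
                 weighted_mvpa_min_week=("weighted_mvpa_min", "sum"))
            .reset_index())
    out = weeks.merge(sums, on=["participant_id", "week_index"], how="left")
    for col in ("mvpa_min_week", "vpa_min_week", "weighted_mvpa_min_week"):
        out[col] = out[col].fillna(0).astype(int)
    meets_mvpa = out["mvpa_min_week"] >= cfg.weekly_mvpa_min
    meets_vpa = out["vpa_min_week"] >= cfg.weekly_vpa_min
    out["meets_mvpa_guideline"] = meets_mvpa.astype("boolean").mask(~out["valid_week"])
    out["meets_vpa_guideline"] = meets_vpa.astype("boolean").mask(~out["valid_week"])
    return out


def participant_adherence(weeks: pd.DataFrame, rule: str = "mvpa150",
                          week_fraction: float = 0.5,
                          ) -> Tuple[Optional[bool], Optional[float]]:
    """Adherence for one participant: (adherent, fraction of valid weeks).

    ``rule`` is ``mvpa150`` or ``vpa75``.  The denominator is valid weeks
    only; with zero valid weeks the participant is non-evaluable and
    ``(None, None)`` is returned.
    """
    if rule not in ("mvpa150", "vpa75"):
        raise ValueError(f"unknown adherence rule {rule!r}")
    flag_col = ("meets_mvpa_guideline" if rule == "mvpa150"
                else "meets_vpa_guideline")
    valid = weeks[weeks["valid_week"]]
    if valid.empty:
        return None, None
    met = valid[flag_col].astype(bool).sum()
    fraction = met / len(valid)
    return bool(fraction >= week_fraction), float(fraction)


@dataclass
class AdherenceSummary:
    """Cohort guideline-adherence prevalence with its 95% interval."""

    n_evaluable: int
    n_meeting: int
    prevalence: float
    ci_low: float
    ci_high: float
    per_participant: Dict[str, float] = field(default_factory=dict)

    @property
    def prevalence_pct(self) -> int:
        return round_half_up(100 * self.prevalence)

    @property
    def ci_low_pct(self) -> int:
        return round_half_up(100 * self.ci_low)

    @property
    def ci_high_pct(self) -> int:
        return round_half_up(100 * self.ci_high)


def cohort_prevalence(adherence_flags: Dict[str, Optional[bool]],
                      fractions: Optional[Dict[str, float]] = None,
                      cfg: Optional[AdherenceConfig] = None,
                      ) -> AdherenceSummary:
    """Prevalence of adherence among evaluable participants.

    ``adherence_flags`` maps participant id to True/False, or None for
    non-evaluable participants (excluded from the denominator).
    """
    cfg = cfg or AdherenceConfig()
    evaluable = {p: f for p, f in adherence_flags.items() if f is not None}
    if not evaluable:
        raise ValueError("no evaluable participants")
    n = len(evaluable)
    x = sum(evaluable.values())
    ci_fn = (wilson_interval if cfg.ci_method == "wilson"
             else clopper_pearson_interval)
    low, high = ci_fn(x, n)
    return AdherenceSummary(
        n_evaluable=n, n_meeting=x, prevalence=x / n,
        ci_low=low, ci_high=high,
        per_participant=dict(fractions or {}))


def cohort_adherence(week_summaries: pd.DataFrame, rule: str = "mvpa150",
                     cfg: Optional[AdherenceConfig] = None,
                     ) -> AdherenceSummary:
    """Prevalence over a whole cohort's week summaries."""
    cfg = cfg or AdherenceConfig()
    flags, fracs = {}, {}
    for pid, grp in week_summaries.groupby("participant_id", sort=True):
        adherent, frac = participant_adherence(grp, rule, cfg.week_fraction)
        flags[pid] = adherent
        if frac is not None:
            fracs[pid] = frac
    return cohort_prevalence(flags, fracs, cfg)


def daily_goal_stats(day_summaries: pd.DataFrame, goal_min: int = 30,
                     ) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-participant attainment of a daily MVPA goal over valid days.

    Returns a per-participant table (ever_met, fraction of valid days met)
    and a cohort summary: how many participants ever met the goal, the
    percent they represent, and — among those — the mean fraction of days
    on which the goal was met.
    """
    valid = day_summaries[day_summaries["valid"]]
    per = (valid.assign(met=valid["mvpa_min"] >= goal_min)
           .groupby("participant_id", sort=True)
           .agg(n_valid_days=("met", "size"), n_days_met=("met", "sum"))
           .reset_index())
    per["ever_met"] = per["n_days_met"] > 0
    per["fraction_met"] = per["n_days_met"] / per["n_valid_days"]
    n = len(per)
    ever = per[per["ever_met"]]
    summary = {
        "n_participants": n,
        "n_ever_met": int(len(ever)),
        "pct_ever_met": round_half_up(100 * len(ever) / n) if n else 0,
        "mean_fraction_among_ever_met":
            float(ever["fraction_met"].mean()) if len(ever) else float("nan"),
    }
    return per, summary


def person_day_summary(day_summaries: pd.DataFrame) -> Dict[str, float]:
    """Analyzed person-day bookkeeping: totals and mean days per participant."""
    valid = day_summaries[day_summaries["valid"]]
    n_participants = valid["participant_id"].nunique()
    n_days = int(len(valid))
    mean_days = n_days / n_participants if n_participants else float("nan")
    return {"n_participants": int(n_participants),
            "n_person_days": n_days,
            "mean_days_per_participant": round_half_up(mean_days)
            if n_participants else 0}
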