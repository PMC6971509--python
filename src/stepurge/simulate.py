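"""Synthetic smoker-cohort generator.

Emulates the structure the downstream analysis assumes, for a cohort of
adult smokers wearing a step-and-heart-rate tracker for up to 12 weeks with
thrice-daily urge prompts:

* demographics drawn to approximate the study margins (57% women, 49%
  nonwhite, 38% obese, 53% high baseline IPAQ, 36% smoking >10/day);
* recording durations in three strata — full 12 weeks, partial 6-12 weeks,
  and short spans that fail the 6-week inclusion rule (default mix 45/8/7
  per 60 enrolled);
* per day an overnight unrecorded block plus Poisson-distributed daytime
  nonwear gaps of 30-180 min; recorded minutes carry heart-rate presence;
* step cadences laid down as alternating sedentary/light/brisk bouts so all
  four cadence bands are populated, with a share of brisk minutes at
  vigorous cadence (>=130 steps/min);
* a day-level urge process: latent mean daily urge
  ``b0_i + beta_mvpa_per30 * (MVPA_d / 30) + e_d`` with participant random
  intercepts, AR(1) day-to-day residuals and participant-specific residual
  SDs (heteroscedasticity); each answered prompt reports the latent value
  plus response noise, rounded and clamped to the 1-9 Likert scale.

The day-level layer is exposed separately (:func:`simulate_model_frame`)
for model-calibration studies that do not need minute-level expansion; it
is the identical stochastic process the full cohort generator uses.  One
global seed drives a per-participant seed stream, so enlarging the cohort
never perturbs earlier participants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as _date, datetime, timedelta
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as sio
from .config import minutes_to_hhmm

BASE_DATE = _date(2016, 4, 11)

# cohort demographic margins the generator targets
P_WOMAN = 0.57
P_NONWHITE = 0.49
P_EDUCATION = (0.15, 0.55, 0.30)
P_BMI_CLASS = (12 / 53, 21 / 53, 20 / 53)   # normal / overweight / obese
P_IPAQ = (0.11, 0.36, 0.53)
P_LIGHT_SMOKER = 0.64                   # <=10 cigarettes/day

MALE_MVPA_FACTOR = 1.8
OBESE_MVPA_FACTOR = 0.5
_MVPA_NORM = ((1 - P_WOMAN) * MALE_MVPA_FACTOR + P_WOMAN) * \
    (P_BMI_CLASS[2] * OBESE_MVPA_FACTOR + (1 - P_BMI_CLASS[2]))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the study conditions."""

    n_participants: int = 60
    n_weeks: int = 12
    seed: int = 0
    beta_mvpa_per30: float = 0.0        # urge units per 30 MVPA-min/day
    sigma_intercept: float = 0.8        # SD of participant intercepts
    rho_ar1: float = 0.3                # day-to-day residual correlation
    sigma_resid_range: Tuple[float, float] = (0.4, 0.9)
    mean_daily_mvpa_min: float = 10.0   # cohort-level target
    wear_gap_rate: float = 0.3          # expected daytime gaps per day
    nonwear_day_prob: float = 0.18      # poor-wear days (device mostly off)
    dropout_week_range: Tuple[int, int] = (6, 12)
    p_partial: float = 8 / 60           # stop within dropout_week_range
    p_short: float = 7 / 60             # span below the inclusion minimum
    short_span_week_range: Tuple[int, int] = (2, 5)
    prompt_miss_prob: float = 0.08
    urge_baseline_mean: float = 5.0
    response_noise_sd: float = 0.7
    vpa_fraction: float = 0.25          # share of brisk minutes >= vigorous
    covariate_effects: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_weeks < 1:
            raise ValueError("n_participants and n_weeks must be >= 1")
        if not 0 <= self.rho_ar1 < 1:
            raise ValueError("rho_ar1 must be in [0, 1)")
        lo, hi = self.sigma_resid_range
        if lo > hi or lo < 0:
            raise ValueError("sigma_resid_range must be ordered and >= 0")
        if not 0 <= self.prompt_miss_prob <= 1:
            raise ValueError("prompt_miss_prob must be a probability")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("sigma_resid_range", "dropout_week_range",
                    "short_span_week_range"):
            if key in raw and isinstance(raw[key], list):
                raw = {**raw, key: tuple(raw[key])}
        return cls(**raw)


@dataclass
class Cohort:
    profiles: pd.DataFrame
    minutes: pd.DataFrame
    urges: pd.DataFrame
    truth_days: pd.DataFrame
    truth_participants: pd.DataFrame
    config: SimulationConfig


def _draw_profile(rng: np.random.Generator, pid: str) -> dict:
    sex = "woman" if rng.random() < P_WOMAN else "man"
    race = "nonwhite" if rng.random() < P_NONWHITE else "white"
    education = sio.EDUCATION_LEVELS[rng.choice(3, p=P_EDUCATION)]
    bmi_class = rng.choice(3, p=P_BMI_CLASS)
    bmi = float(np.round(rng.uniform(*[(19.0, 24.9), (25.0, 29.9),
                                       (30.0, 40.0)][bmi_class]), 1))
    age = int(np.clip(np.round(rng.normal(40, 12)), 18, 65))
    if rng.random() < P_LIGHT_SMOKER:
        cigarettes = int(rng.integers(3, 11))
    else:
        cigarettes = int(rng.integers(11, 31))
    ipaq = sio.IPAQ_LEVELS[rng.choice(3, p=P_IPAQ)]
    prompts = (int(rng.integers(420, 541)),      # 07:00-09:00
               int(rng.integers(690, 811)),      # 11:30-13:30
               int(rng.integers(1050, 1171)))    # 17:30-19:30
    return {
        "participant_id": pid, "age": age, "sex": sex, "race": race,
        "education": education, "bmi": bmi, "cigarettes_per_day": cigarettes,
        "ipaq_category": ipaq,
        "prompt_time_1": minutes_to_hhmm(prompts[0]),
        "prompt_time_2": minutes_to_hhmm(prompts[1]),
        "prompt_time_3": minutes_to_hhmm(prompts[2]),
        "_prompt_minutes": prompts,
    }


def _draw_duration_weeks(rng: np.random.Generator,
                         cfg: SimulationConfig) -> int:
    u = rng.random()
    if u < cfg.p_short:
        lo, hi = cfg.short_span_week_range
        return int(rng.integers(lo, hi + 1))
    if u < cfg.p_short + cfg.p_partial:
        lo, hi = cfg.dropout_week_range
        return int(rng.integers(lo, hi))      # strictly below the full term
    return cfg.n_weeks


def _participant_days(rng: np.random.Generator, profile: dict, n_days: int,
                      cfg: SimulationConfig) -> pd.DataFrame:
    """Day-level truth for one participant: activity, latent urge, responses."""
    man = profile["sex"] == "man"
    obese = profile["bmi"] >= 30
    frailty = float(np.exp(rng.normal(0.0, 0.6) - 0.18))
    mu = (cfg.mean_daily_mvpa_min / _MVPA_NORM * frailty
          * (MALE_MVPA_FACTOR if man else 1.0)
          * (OBESE_MVPA_FACTOR if obese else 1.0))
    mvpa = np.minimum(np.round(rng.gamma(0.9, mu / 0.9, n_days)),
                      150).astype(int)
    band2_mu = 24.0 * (1.6 if man else 1.0)
    band2 = np.round(rng.gamma(1.5, band2_mu / 1.5, n_days)).astype(int)
    band1 = np.clip(np.round(rng.normal(200, 40, n_days)), 30, 400).astype(int)

    effects = sum(cfg.covariate_effects.get(k, 0.0) * v for k, v in (
        ("sex_woman", float(not man)), ("age", profile["age"]),
        ("bmi", profile["bmi"]), ("race_nonwhite",
                                  float(profile["race"] == "nonwhite")),
        ("cigarettes_per_day", profile["cigarettes_per_day"]),
        ("ipaq_high", float(profile["ipaq_category"] == "high"))))
    b0 = cfg.urge_baseline_mean + rng.normal(0.0, cfg.sigma_intercept) + effects
    sigma_i = rng.uniform(*cfg.sigma_resid_range)
    e = np.empty(n_days)
    e[0] = rng.normal(0.0, sigma_i)
    innov = rng.normal(0.0, sigma_i * np.sqrt(1 - cfg.rho_ar1 ** 2),
                       n_days - 1) if n_days > 1 else np.empty(0)
    for d in range(1, n_days):
        e[d] = cfg.rho_ar1 * e[d - 1] + innov[d - 1]
    latent = b0 + cfg.beta_mvpa_per30 * (mvpa / 30.0) + e

    answered = rng.random((n_days, 3)) >= cfg.prompt_miss_prob
    noise = rng.normal(0.0, cfg.response_noise_sd, (n_days, 3))
    values = np.clip(np.round(latent[:, None] + noise), 1, 9).astype(int)

    return pd.DataFrame({
        "participant_id": profile["participant_id"],
        "date": [BASE_DATE + timedelta(days=d) for d in range(n_days)],
        "true_mvpa_min": mvpa,
        "true_band2_min": band2,
        "true_band1_min": band1,
        "latent_urge": latent,
        "answered_1": answered[:, 0], "answered_2": answered[:, 1],
        "answered_3": answered[:, 2],
        "urge_1": values[:, 0], "urge_2": values[:, 1], "urge_3": values[:, 2],
        "b0": b0, "sigma_resid": sigma_i,
    })


def _day_layer(cfg: SimulationConfig):
    """Per-participant profiles, durations and day-level truth tables."""
    root = np.random.SeedSequence(cfg.seed)
    out = []
    for i, child in enumerate(root.spawn(cfg.n_participants)):
        day_seed, minute_seed = child.spawn(2)
        rng = np.random.default_rng(day_seed)
        pid = f"P{i + 1:03d}"
        profile = _draw_profile(rng, pid)
        weeks = _draw_duration_weeks(rng, cfg)
        days = _participant_days(rng, profile, weeks * 7, cfg)
        out.append((profile, weeks, days, minute_seed))
    return out


def simulate_model_frame(cfg: SimulationConfig,
                         ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Day-level analysis frame straight from the generator's urge layer.

    Returns (frame, truth_days).  The frame has the same columns
    :func:`stepurge.urge_model.build_model_frame` produces, with every day
    treated as a valid wear day; it is meant for calibration studies of the
    urge model where minute-level expansion adds nothing.
    """
    frames, truths = [], []
    for profile, weeks, days, _ in _day_layer(cfg):
        answered = days[["answered_1", "answered_2", "answered_3"]].to_numpy()
        vals = days[["urge_1", "urge_2", "urge_3"]].to_numpy(float)
        n_resp = answered.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_urge = np.where(n_resp > 0,
                                 (vals * answered).sum(axis=1)
                                 / np.maximum(n_resp, 1), np.nan)
        f = pd.DataFrame({
            "participant_id": profile["participant_id"],
            "date": days["date"],
            "n_responses": n_resp.astype(int),
            "mean_urge": mean_urge,
            "mvpa_min": days["true_mvpa_min"],
        })
        f["mvpa30"] = f["mvpa_min"] / 30.0
        f["age"] = float(profile["age"])
        f["sex_woman"] = float(profile["sex"] == "woman")
        f["race_nonwhite"] = float(profile["race"] == "nonwhite")
        f["edu_some_college"] = float(profile["education"] == "some-college")
        f["edu_bachelors"] = float(
            profile["education"] == "bachelors-or-higher")
        f["bmi"] = float(profile["bmi"])
        f["cigarettes_per_day"] = float(profile["cigarettes_per_day"])
        f["ipaq_high"] = float(profile["ipaq_category"] == "high")
        frames.append(f[f["n_responses"] > 0])
        truths.append(days)
    frame = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    return frame, truth


def _place_bouts(labels: np.ndarray, band: int, n_minutes: int,
                 bout_range: Tuple[int, int],
                 rng: np.random.Generator) -> None:
    """Mark ``n_minutes`` free slots with ``band``, in contiguous bouts."""
    need = n_minutes
    while need > 0:
        free = labels == 0
        idx = np.flatnonzero(free)
        if idx.size == 0:
            break
        want = min(int(rng.integers(*bout_range)), need)
        # contiguous free runs
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        runs = np.split(idx, breaks)
        lengths = np.array([len(r) for r in runs])
        eligible = np.flatnonzero(lengths >= want)
        if eligible.size:
            run = runs[int(rng.choice(eligible))]
            start = int(rng.integers(0, len(run) - want + 1))
            labels[run[start:start + want]] = band
            need -= want
        else:
            run = runs[int(np.argmax(lengths))]
            labels[run] = band
            need -= len(run)


def _expand_minutes(rng: np.random.Generator, days: pd.DataFrame,
                    profile: dict, cfg: SimulationConfig,
                    recorded_counts: Optional[list] = None) -> pd.DataFrame:
    """Minute-level records for one participant from the day-level truth."""
    recs = []
    if recorded_counts is None:
        recorded_counts = []
    for row in days.itertuples(index=False):
        wake = int(rng.integers(380, 561))        # 06:20-09:20
        sleep = int(rng.integers(1330, 1432))     # 22:10-23:51
        recorded = np.ones(1440, dtype=bool)
        recorded[:wake] = False
        recorded[sleep:] = False
        for _ in range(rng.poisson(cfg.wear_gap_rate)):
            length = int(rng.integers(30, 181))
            start = int(rng.integers(600, 1320 - length + 1))
            recorded[start:start + length] = False
        if rng.random() < cfg.nonwear_day_prob:
            # poor-wear day: a long morning gap plus an early removal for
            # the rest of the day -- typically fails both exclusion rules
            g1 = int(rng.integers(90, 181))
            s1 = int(rng.integers(600, 721))
            recorded[s1:s1 + g1] = False
            off_at = int(rng.integers(s1 + g1 + 30, 961))
            recorded[off_at:] = False
        slots = np.flatnonzero(recorded)
        labels = np.zeros(slots.size, dtype=np.int64)
        _place_bouts(labels, 3, min(row.true_mvpa_min, slots.size),
                     (5, 21), rng)
        _place_bouts(labels, 2, min(row.true_band2_min,
                                    int((labels == 0).sum())), (3, 11), rng)
        free = np.flatnonzero(labels == 0)
        n1 = min(row.true_band1_min, free.size)
        if n1 > 0:
            labels[rng.choice(free, size=n1, replace=False)] = 1

        steps = np.zeros(slots.size, dtype=np.int64)
        b3 = labels == 3
        if b3.any():
            vig = rng.random(int(b3.sum())) < cfg.vpa_fraction
            s3 = np.where(vig, rng.integers(130, 181, vig.size),
                          rng.integers(100, 130, vig.size))
            steps[b3] = s3
        b2 = labels == 2
        steps[b2] = rng.integers(60, 100, int(b2.sum()))
        b1 = labels == 1
        steps[b1] = rng.integers(1, 60, int(b1.sum()))

        # device labels emulate an opaque intensity algorithm that promotes
        # lower cadences than the 100 steps/min threshold
        thr3 = rng.normal(110, 25, slots.size)
        thr2 = rng.normal(45, 15, slots.size)
        device = np.zeros(slots.size, dtype=np.int64)
        device[steps > 0] = 1
        device[steps >= thr2] = 2
        device[steps >= thr3] = 3

        day_start = datetime.combine(row.date, datetime.min.time())
        recs.append(pd.DataFrame({
            "participant_id": profile["participant_id"],
            "timestamp": day_start + pd.to_timedelta(slots, unit="m"),
            "steps": steps,
            "hr_present": True,
            "device_intensity": pd.array(device, dtype="Int64"),
        }))
        recorded_counts.append(slots.size)
    return pd.concat(recs, ignore_index=True)


def simulate_cohort(cfg: Optional[SimulationConfig] = None) -> Cohort:
    """Generate a full cohort: profiles, minute records, urges and truth.

    Identical config (including seed) yields identical output.  The truth
    tables record each participant's latent parameters and each day's true
    band minutes and latent urge; they exist for tests and are never read
    by the analysis pipeline.
    """
    cfg = cfg or SimulationConfig()
    profiles, minutes, urges = [], [], []
    truth_days, truth_participants = [], []
    for profile, weeks, days, minute_seed in _day_layer(cfg):
        rng_min = np.random.default_rng(minute_seed)
        counts: list = []
        minutes.append(_expand_minutes(rng_min, days, profile, cfg, counts))
        days = days.assign(n_recorded_minutes=counts)
        prompts = profile.pop("_prompt_minutes")
        for row in days.itertuples(index=False):
            day_start = datetime.combine(row.date, datetime.min.time())
            for k, minute in enumerate(prompts):
                if getattr(row, f"answered_{k + 1}"):
                    urges.append({
                        "participant_id": profile["participant_id"],
                        "timestamp": day_start + timedelta(minutes=minute),
                        "urge": int(getattr(row, f"urge_{k + 1}")),
                    })
        profiles.append(profile)
        truth_days.append(days.drop(columns=["b0", "sigma_resid"]))
        truth_participants.append({
            "participant_id": profile["participant_id"],
            "n_weeks_recorded": weeks,
            "b0": float(days["b0"].iloc[0]),
            "sigma_resid": float(days["sigma_resid"].iloc[0]),
        })
    urge_df = pd.DataFrame(urges, columns=["participant_id", "timestamp",
                                           "urge"])
    urge_df["timestamp"] = pd.to_datetime(urge_df["timestamp"])
    return Cohort(
        profiles=pd.DataFrame(profiles)[sio.PROFILE_COLUMNS],
        minutes=pd.concat(minutes, ignore_index=True),
        urges=urge_df,
        truth_days=pd.concat(truth_days, ignore_index=True),
        truth_participants=pd.DataFrame(truth_participants),
        config=cfg)


def write_cohort(cohort: Cohort, directory) -> Dict[str, Path]:
    """Write the three pipeline CSVs plus the truth tables (tests only)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": directory / "profiles.csv",
        "minutes": directory / "minutes.csv",
        "urges": directory / "urges.csv",
        "truth_days": directory / "truth_days.csv",
        "truth_participants": directory / "truth_participants.csv",
    }
    sio.write_profiles(cohort.profiles, paths["profiles"])
    sio.write_minutes(cohort.minutes, paths["minutes"])
    sio.write_urges(cohort.urges, paths["urges"])
    cohort.truth_days.to_csv(paths["truth_days"], index=False)
    cohort.truth_participants.to_csv(paths["truth_participants"], index=False)
    return paths
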