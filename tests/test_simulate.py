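"""Generator contracts: determinism, structure, and statistical fidelity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stepurge import (SimulationConfig, classify_days, read_minutes,
                      simulate_cohort, simulate_model_frame, write_cohort)
from tests.oracles import lag1_autocorr


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_participants=0)
    with pytest.raises(ValueError):
        SimulationConfig(n_weeks=0)
    with pytest.raises(ValueError):
        SimulationConfig(rho_ar1=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(sigma_resid_range=(0.9, 0.4))
    with pytest.raises(ValueError):
        SimulationConfig.from_dict({"bogus_knob": 1})


def test_same_seed_gives_byte_identical_csvs(tmp_path):
    cfg = SimulationConfig(n_participants=3, n_weeks=1, seed=5)
    a, b = tmp_path / "a", tmp_path / "b"
    write_cohort(simulate_cohort(cfg), a)
    write_cohort(simulate_cohort(cfg), b)
    for name in ("profiles.csv", "minutes.csv", "urges.csv",
                 "truth_days.csv"):
        assert (a / name).read_bytes() == (b / name).read_bytes()


def test_seed_stream_is_stable_under_cohort_growth():
    small = simulate_cohort(SimulationConfig(n_participants=2, n_weeks=1,
                                             seed=9))
    large = simulate_cohort(SimulationConfig(n_participants=4, n_weeks=1,
                                             seed=9))
    for df_s, df_l in ((small.minutes, large.minutes),
                       (small.urges, large.urges)):
        sub = df_l[df_l["participant_id"].isin(["P001", "P002"])]
        pd.testing.assert_frame_equal(df_s.reset_index(drop=True),
                                      sub.reset_index(drop=True))


def test_gap_free_config_every_day_valid_three_urges():
    cfg = SimulationConfig(n_participants=4, n_weeks=2, seed=11,
                           wear_gap_rate=0.0, nonwear_day_prob=0.0,
                           prompt_miss_prob=0.0,
                           p_short=0.0, p_partial=0.0)
    cohort = simulate_cohort(cfg)
    days = classify_days(cohort.minutes)
    assert days["valid"].all()
    per_day = cohort.urges.groupby(
        [cohort.urges["participant_id"],
         cohort.urges["timestamp"].dt.date]).size()
    assert (per_day == 3).all()
    assert len(per_day) == 4 * 14


def test_minute_bands_respect_construction(small_cohort):
    m = small_cohort.minutes
    assert (m["steps"] >= 0).all() and (m["steps"] <= 300).all()
    per_day = (m.assign(date=m["timestamp"].dt.date,
                        brisk=m["steps"] >= 100)
               .groupby(["participant_id", "date"])["brisk"].sum())
    truth = small_cohort.truth_days.set_index(["participant_id", "date"])
    joined = truth.join(per_day.rename("measured"))
    assert (joined["measured"] == joined["true_mvpa_min"]).all()


def test_minute_rows_equal_recorded_minutes_in_truth(small_cohort):
    assert len(small_cohort.minutes) == \
        small_cohort.truth_days["n_recorded_minutes"].sum()


def test_profiles_pass_reader_validation(tmp_path, small_cohort):
    # written output must round-trip through the strict readers
    paths = write_cohort(small_cohort, tmp_path)
    assert len(read_minutes(paths["minutes"])) == len(small_cohort.minutes)
    assert len(pd.read_csv(paths["profiles"])) == 8


def test_null_effect_recovers_zero_slope():
    cfg = SimulationConfig(n_participants=30, n_weeks=6, seed=21,
                           beta_mvpa_per30=0.0, p_short=0.0, p_partial=0.0)
    frame, _ = simulate_model_frame(cfg)
    # within-participant regression removes intercept heterogeneity
    d = frame.copy()
    for col in ("mean_urge", "mvpa30"):
        d[col] -= d.groupby("participant_id")[col].transform("mean")
    x, y = d["mvpa30"].to_numpy(), d["mean_urge"].to_numpy()
    slope = (x @ y) / (x @ x)
    se = np.sqrt(np.sum((y - slope * x) ** 2) / (len(x) - 1) / (x @ x))
    assert abs(slope) < 2 * se + 0.02


def test_nonnull_effect_shifts_urge_downward():
    base = dict(n_participants=30, n_weeks=6, seed=21,
                p_short=0.0, p_partial=0.0)
    null, _ = simulate_model_frame(SimulationConfig(beta_mvpa_per30=0.0,
                                                    **base))
    neg, _ = simulate_model_frame(SimulationConfig(beta_mvpa_per30=-0.5,
                                                   **base))
    # identical streams: the only difference is the exposure effect
    assert neg["mean_urge"].mean() < null["mean_urge"].mean()


def test_clamping_bias_is_bounded():
    # sigma choices keep the latent scale well inside [2, 8]
    cfg = SimulationConfig(n_participants=30, n_weeks=6, seed=13,
                           sigma_intercept=0.5,
                           sigma_resid_range=(0.3, 0.5),
                           p_short=0.0, p_partial=0.0)
    frame, truth = simulate_model_frame(cfg)
    merged = frame.merge(truth, on=["participant_id", "date"])
    assert np.percentile(merged["latent_urge"], [1, 99]).tolist() == \
        pytest.approx([2, 8], abs=2)  # sanity on the latent range
    bias = (merged["mean_urge"] - merged["latent_urge"]).mean()
    assert abs(bias) < 0.1


def test_day_residual_autocorrelation_matches_rho():
    cfg = SimulationConfig(n_participants=60, n_weeks=24, seed=17,
                           rho_ar1=0.4, p_short=0.0, p_partial=0.0)
    _, truth = simulate_model_frame(cfg)  # 60 x 168 > 10,000 days
    series = []
    for _, grp in truth.groupby("participant_id"):
        resid = grp["latent_urge"] - grp["b0"] \
            - cfg.beta_mvpa_per30 * grp["true_mvpa_min"] / 30.0
        series.append(resid.to_numpy())
    assert lag1_autocorr(series) == pytest.approx(0.4, abs=0.05)


def test_demographic_margins_approximate_study():
    cfg = SimulationConfig(n_participants=300, n_weeks=1, seed=3)
    frame, _ = simulate_model_frame(cfg)
    p = frame.groupby("participant_id").first()
    assert p["sex_woman"].mean() == pytest.approx(0.57, abs=0.08)
    assert p["race_nonwhite"].mean() == pytest.approx(0.49, abs=0.08)
    assert (p["bmi"] >= 30).mean() == pytest.approx(0.38, abs=0.08)
    assert (p["cigarettes_per_day"] > 10).mean() == \
        pytest.approx(0.36, abs=0.08)
    assert (p["cigarettes_per_day"] >= 3).all()


def test_duration_strata_emulate_study_flow():
    cfg = SimulationConfig(n_participants=200, n_weeks=12, seed=19)
    _, truth = simulate_model_frame(cfg)
    weeks = truth.groupby("participant_id").size() / 7
    assert ((weeks == 12).mean() == pytest.approx(45 / 60, abs=0.1))
    assert (weeks < 6).mean() == pytest.approx(7 / 60, abs=0.07)
    assert weeks.isin(range(2, 13)).all()
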