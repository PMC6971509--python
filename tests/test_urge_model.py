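"""Urge aggregation, frame construction and the repeated-measures fit."""

from __future__ import annotations

import warnings
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from stepurge import (ModelSpec, SimulationConfig, build_model_frame,
                      classify_days, daily_mean_urge, fit_urge_model,
                      interaction_screen, simulate_cohort,
                      simulate_model_frame, stratified_fit, summarize_days)
from stepurge.urge_model import (DegenerateDesignError, add_moderator_columns,
                                 final_model_spec)


def _urges(values, pid="P001", day="2016-05-02"):
    base = datetime.fromisoformat(day)
    return pd.DataFrame({
        "participant_id": pid,
        "timestamp": [base + timedelta(hours=8 + 4 * i)
                      for i in range(len(values))],
        "urge": values,
    })


@pytest.mark.parametrize("values,expected", [
    ([3, 5, 7], 5.0), ([9], 9.0), ([1, 2, 2, 4], 2.25),
])
def test_daily_mean_urge(values, expected):
    out = daily_mean_urge(_urges(values))
    assert len(out) == 1
    assert out["mean_urge"].iloc[0] == expected
    assert out["n_responses"].iloc[0] == len(values)


def test_daily_mean_urge_groups_by_day():
    df = pd.concat([_urges([2, 4], day="2016-05-02"),
                    _urges([8], day="2016-05-03")])
    out = daily_mean_urge(df)
    assert out["mean_urge"].tolist() == [3.0, 8.0]


def _cohort_frames(cohort):
    dw = classify_days(cohort.minutes)
    ds = summarize_days(cohort.minutes, dw)
    ud = daily_mean_urge(cohort.urges)
    return dw, ds, ud


def test_build_model_frame_joins_and_drops(small_cohort):
    dw, ds, ud = _cohort_frames(small_cohort)
    frame, log = build_model_frame(ud, ds, small_cohort.profiles)
    # oracle join: urge-days merged to valid day summaries
    valid = ds[ds["valid"]][["participant_id", "date"]]
    expected = len(ud.merge(valid, on=["participant_id", "date"]))
    assert len(frame) == expected == log["person_days_modelled"]
    assert log["dropped_invalid_day"] == \
        len(ud) - expected - log["dropped_no_wear_day"]
    # invalid days are absent
    invalid = ds[~ds["valid"]][["participant_id", "date"]]
    assert frame.merge(invalid, on=["participant_id", "date"]).empty


def test_build_model_frame_requires_profiles(small_cohort):
    dw, ds, ud = _cohort_frames(small_cohort)
    profiles = small_cohort.profiles.iloc[:-1]
    with pytest.raises(ValueError, match="without profiles"):
        build_model_frame(ud, ds, profiles)


def test_constant_exposure_is_degenerate(small_cohort):
    dw, ds, ud = _cohort_frames(small_cohort)
    frame, _ = build_model_frame(ud, ds, small_cohort.profiles)
    frame["mvpa30"] = 0.0
    with pytest.raises(DegenerateDesignError):
        fit_urge_model(frame)


@pytest.fixture(scope="module")
def medium_frame():
    cfg = SimulationConfig(n_participants=35, n_weeks=6, seed=23,
                           beta_mvpa_per30=-0.3,
                           p_short=0.0, p_partial=0.0)
    frame, _ = simulate_model_frame(cfg)
    return frame


def test_ri_only_limit_matches_random_intercept_oracle(medium_frame):
    """With rho=0 and a common scale the fit must coincide with an ordinary
    random-intercept mixed model (independent implementation)."""
    import statsmodels.formula.api as smf
    ours = fit_urge_model(medium_frame, ModelSpec(mode="ri-only"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        oracle = smf.mixedlm(
            "mean_urge ~ mvpa30 + age + sex_woman + race_nonwhite"
            " + edu_some_college + edu_bachelors + bmi + cigarettes_per_day"
            " + ipaq_high",
            medium_frame, groups=medium_frame["participant_id"],
        ).fit(reml=True)
    assert ours.params.loc["mvpa30", "coef"] == \
        pytest.approx(oracle.params["mvpa30"], abs=1e-6)
    assert ours.params.loc["intercept", "coef"] == \
        pytest.approx(oracle.params["Intercept"], abs=1e-6)
    assert ours.intercept_var == pytest.approx(oracle.cov_re.iloc[0, 0],
                                               abs=1e-4)


def test_exposure_rescaling_is_exact(medium_frame):
    per30 = fit_urge_model(medium_frame)
    frame_min = medium_frame.copy()
    spec_min = ModelSpec(exposure="mvpa_min")
    per_min = fit_urge_model(frame_min, spec_min)
    c30 = per30.params.loc["mvpa30"]
    c1 = per_min.params.loc["mvpa_min"]
    assert c30["coef"] == pytest.approx(30 * c1["coef"], rel=1e-4)
    assert c30["p"] == pytest.approx(c1["p"], abs=1e-4)


def test_orthogonal_covariate_leaves_exposure_unchanged(medium_frame):
    base = fit_urge_model(medium_frame, ModelSpec(mode="ar1-common"))
    fixed = {"rho": base.rho_ar1,
             "psi": base.intercept_var / base.sigma2}
    ref = fit_urge_model(medium_frame, ModelSpec(mode="ar1-common"),
                         fixed=fixed)
    # build a covariate orthogonal (under the fitted V^-1) to the design
    # and the outcome, by regressing noise on them in the GLS sense via a
    # plain fit of noise as outcome
    rng = np.random.default_rng(0)
    z = rng.normal(size=len(medium_frame))
    # GLS-project z on [1, X, y] (fit z as outcome with y as covariate);
    # the residual is V^-1-orthogonal to the whole original design + outcome
    spec_z = ModelSpec(covariates=tuple(ModelSpec().covariates) + ("_y",))
    aug2 = medium_frame.assign(_y=medium_frame["mean_urge"], mean_urge=z)
    zres_fit = fit_urge_model(aug2, spec_z, fixed=fixed)
    pred = sum(zres_fit.params.loc[t, "coef"]
               * (1.0 if t == "intercept" else aug2[t])
               for t in zres_fit.params.index)
    z_orth = z - pred
    aug3 = medium_frame.assign(_z=z_orth)
    spec3 = ModelSpec(covariates=tuple(ModelSpec().covariates) + ("_z",))
    with_z = fit_urge_model(aug3, spec3, fixed=fixed)
    assert with_z.params.loc["mvpa30", "coef"] == \
        pytest.approx(ref.params.loc["mvpa30", "coef"], abs=1e-6)


def test_strong_interaction_is_kept():
    cfg = SimulationConfig(n_participants=40, n_weeks=6, seed=29,
                           p_short=0.0, p_partial=0.0)
    frame, _ = simulate_model_frame(cfg)
    # inject a strong sex-by-exposure interaction into the outcome
    frame = frame.assign(
        mean_urge=frame["mean_urge"]
        - 0.8 * frame["mvpa30"] * frame["sex_woman"])
    screen = interaction_screen(frame)
    row = screen.set_index("moderator").loc["sex_woman"]
    assert row["keep"] and row["p_interaction"] < 0.01


def test_final_spec_contains_only_kept_interactions():
    screen = pd.DataFrame({
        "moderator": ["age40", "sex_woman", "bmi30", "ipaq_high"],
        "p_interaction": [0.41, 0.15, 0.90, 0.32],
        "keep": [False, False, False, False],
    })
    assert final_model_spec(screen).interactions == ()
    screen.loc[1, "keep"] = True
    assert final_model_spec(screen).interactions == ("sex_woman",)


def test_kept_interaction_enters_final_fit(medium_frame):
    frame = add_moderator_columns(medium_frame)
    spec = final_model_spec(pd.DataFrame({
        "moderator": ["bmi30"], "p_interaction": [0.01], "keep": [True]}))
    res = fit_urge_model(frame, spec)
    assert "mvpa30:bmi30" in res.params.index


def test_stratified_fit_counts_and_refusals(medium_frame):
    strata = stratified_fit(medium_frame)
    prof = medium_frame.groupby("participant_id")["cigarettes_per_day"].first()
    for name, rule in (( ">10", lambda c: c > 10), (">=15", lambda c: c >= 15),
                       (">=20", lambda c: c >= 20)):
        res = strata[name]
        assert res.n_participants == int(rule(prof).sum())
        assert res.n_person_days == int(
            rule(medium_frame["cigarettes_per_day"]).sum())
        assert "cigarettes_per_day" not in res.params.index
    with pytest.raises(ValueError, match="at least 2"):
        stratified_fit(medium_frame,
                       rules={">=100": lambda c: c >= 100})


def test_stratum_specific_effect_recovered():
    cfg = SimulationConfig(n_participants=45, n_weeks=8, seed=31,
                           p_short=0.0, p_partial=0.0)
    frame, _ = simulate_model_frame(cfg)
    heavy = frame["cigarettes_per_day"] > 10
    frame = frame.assign(
        mean_urge=frame["mean_urge"] - 0.4 * frame["mvpa30"] * heavy)
    res = stratified_fit(frame, rules={">10": lambda c: c > 10})[">10"]
    c = res.params.loc["mvpa30"]
    assert c["ci_low"] <= -0.4 <= c["ci_high"]
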