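"""End-to-end pipeline: simulate/read -> wear filter -> banding -> adherence
-> urge model -> descriptives, with exclusion accounting at every stage.

Exclusion bookkeeping is the pipeline's core audit trail (cohort ->
participants with sufficient span -> valid days -> valid weeks -> evaluable
participants); every decision is written to the run log with the rule that
made it.  Stages that cannot run on the surviving data (an empty model
frame, zero evaluable participants) degrade to empty-but-valid artifacts
with a logged warning rather than aborting, so degenerate configurations
still produce a complete, inspectable output directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import adherence as adh
from . import descriptives as desc
from . import io as sio
from . import urge_model as um
from . import wear
from .config import PipelineConfig
from .intensity import compare_device_intensity, summarize_days
from .simulate import SimulationConfig, simulate_cohort


@dataclass
class PipelineResult:
    config: PipelineConfig
    day_summaries: pd.DataFrame
    week_summaries: pd.DataFrame
    adherence_mvpa: Optional[adh.AdherenceSummary]
    adherence_vpa: Optional[adh.AdherenceSummary]
    daily_goal: Dict
    person_days: Dict
    model: Optional[um.ModelResult]
    comparison: Optional[pd.DataFrame]
    exclusions: pd.DataFrame
    log: list = field(default_factory=list)


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        cfg = SimulationConfig.from_dict(sim_kwargs)
        cohort = simulate_cohort(cfg)
        return cohort.profiles, cohort.minutes, cohort.urges
    if config.input_dir is None:
        raise ValueError("input_dir is required when simulate is false")
    d = Path(config.input_dir)
    return (sio.read_profiles(d / "profiles.csv"),
            sio.read_minutes(d / "minutes.csv"),
            sio.read_urges(d / "urges.csv"))


def run_pipeline(config: Optional[PipelineConfig] = None,
                 write: bool = True) -> PipelineResult:
    """Run every stage in order and (optionally) write the artifact set."""
    config = config or PipelineConfig()
    log: list = []

    def note(msg: str) -> None:
        log.append(msg)

    try:
        profiles, minutes, urges = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'load': {exc}") from exc
    note(f"load: {len(profiles)} participants, {len(minutes)} minute rows, "
         f"{len(urges)} urge responses")

    try:
        day_wears = wear.classify_days(minutes, config.wear)
        retained, excl = wear.filter_participants(day_wears, config.wear)
        n_dropped_days = int((~day_wears["valid"]).sum())
        note(f"wear filter: {n_dropped_days} of {len(day_wears)} days "
             "excluded (nonwear rule)")
        for row in excl.itertuples(index=False):
            note(f"wear filter: participant {row.participant_id} dropped -- "
                 f"{row.rule} ({row.detail})")
        note(f"wear filter: {len(retained)} of "
             f"{day_wears['participant_id'].nunique()} participants retained")
        day_wears = day_wears[day_wears["participant_id"].isin(retained)]
        minutes = minutes[minutes["participant_id"].isin(retained)]
        urges = urges[urges["participant_id"].isin(retained)]
    except Exception as exc:
        raise RuntimeError(f"stage 'wear_filter': {exc}") from exc

    try:
        day_summaries = summarize_days(minutes, day_wears, config.bands)
        week_shells = wear.mark_weeks(day_wears, config.wear)
        week_summaries = adh.weekly_totals(day_summaries, week_shells,
                                           config.adherence)
        n_valid_weeks = int(week_summaries["valid_week"].sum())
        note(f"weeks: {n_valid_weeks} of {len(week_summaries)} weeks valid "
             f"(>= {config.wear.min_days_per_week} valid days)")
    except Exception as exc:
        raise RuntimeError(f"stage 'intensity': {exc}") from exc

    adherence_mvpa = adherence_vpa = None
    daily_goal: Dict = {}
    person_days = adh.person_day_summary(day_summaries)
    try:
        adherence_mvpa = adh.cohort_adherence(week_summaries, "mvpa150",
                                              config.adherence)
        adherence_vpa = adh.cohort_adherence(week_summaries, "vpa75",
                                             config.adherence)
        _, daily_goal = adh.daily_goal_stats(day_summaries,
                                             config.adherence.daily_goal_min)
        note(f"adherence: {adherence_mvpa.n_meeting}/"
             f"{adherence_mvpa.n_evaluable} adherent (MVPA rule), "
             f"prevalence {adherence_mvpa.prevalence_pct}% "
             f"(95% CI {adherence_mvpa.ci_low_pct}% to "
             f"{adherence_mvpa.ci_high_pct}%)")
    except ValueError as exc:
        note(f"adherence: WARNING skipped -- {exc}")

    model = None
    try:
        urge_days = um.daily_mean_urge(urges) if len(urges) else \
            pd.DataFrame(columns=["participant_id", "date", "n_responses",
                                  "mean_urge"])
        frame, frame_log = um.build_model_frame(urge_days, day_summaries,
                                                profiles)
        note("model frame: "
             + ", ".join(f"{k}={v}" for k, v in frame_log.items()))
        if frame["participant_id"].nunique() >= 2 and len(frame) >= 10:
            spec = um.ModelSpec(mode=config.model_mode)
            model = um.fit_urge_model(frame, spec)
            coef = model.coef("mvpa30")
            note(f"urge model ({model.mode}): MVPA effect per 30 min/day = "
                 f"{coef['coef']:.3f} (95% CI {coef['ci_low']:.3f} to "
                 f"{coef['ci_high']:.3f}, p={coef['p']:.2f}); "
                 f"rho={model.rho_ar1:.2f}")
            if not model.converged:
                note("urge model: WARNING fit did not converge cleanly")
        else:
            note("urge model: WARNING skipped -- too few modellable "
                 "person-days")
    except um.DegenerateDesignError as exc:
        note(f"urge model: WARNING skipped -- degenerate design: {exc}")
    except Exception as exc:
        raise RuntimeError(f"stage 'urge_model': {exc}") from exc

    comparison = None
    try:
        have_days = day_summaries["valid"].any()
        if have_days and day_summaries[day_summaries["valid"]][
                "participant_id"].nunique() >= 4:
            comparison = desc.comparison_table(day_summaries, profiles)
        else:
            note("descriptives: WARNING skipped -- too few participants "
                 "with valid days")
    except ValueError as exc:
        note(f"descriptives: WARNING skipped -- {exc}")

    result = PipelineResult(
        config=config, day_summaries=day_summaries,
        week_summaries=week_summaries, adherence_mvpa=adherence_mvpa,
        adherence_vpa=adherence_vpa, daily_goal=daily_goal,
        person_days=person_days, model=model, comparison=comparison,
        exclusions=excl, log=log)
    if write:
        write_artifacts(result, Path(config.output_dir))
    return result


def write_artifacts(result: PipelineResult, out_dir: Path) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / fname for name, fname in (
        ("days", "day_summaries.csv"), ("weeks", "week_summaries.csv"),
        ("adherence", "adherence.csv"), ("model", "model_coefficients.csv"),
        ("comparison", "group_comparisons.csv"),
        ("report", "report.txt"), ("log", "exclusions.log"))}
    result.day_summaries.to_csv(paths["days"], index=False)
    result.week_summaries.to_csv(paths["weeks"], index=False)

    rows = []
    for rule, summ in (("mvpa150", result.adherence_mvpa),
                       ("vpa75", result.adherence_vpa)):
        if summ is not None:
            rows.append({"rule": rule, "n_evaluable": summ.n_evaluable,
                         "n_meeting": summ.n_meeting,
                         "prevalence_pct": summ.prevalence_pct,
                         "ci_low_pct": summ.ci_low_pct,
                         "ci_high_pct": summ.ci_high_pct})
    pd.DataFrame(rows, columns=["rule", "n_evaluable", "n_meeting",
                                "prevalence_pct", "ci_low_pct",
                                "ci_high_pct"]).to_csv(
        paths["adherence"], index=False)

    if result.model is not None:
        result.model.params.rename_axis("term").to_csv(paths["model"])
    else:
        pd.DataFrame(columns=["term", "coef", "se", "ci_low", "ci_high",
                              "p"]).to_csv(paths["model"], index=False)
    if result.comparison is not None:
        result.comparison.to_csv(paths["comparison"], index=False)
    else:
        pd.DataFrame().to_csv(paths["comparison"], index=False)

    report = ["run summary", "==========="]
    report += [f"person-days analyzed: {result.person_days['n_person_days']} "
               f"over {result.person_days['n_participants']} participants "
               f"(mean {result.person_days['mean_days_per_participant']} "
               "days/participant)"]
    if result.daily_goal:
        report += [f"daily 30-min goal ever met: "
                   f"{result.daily_goal['n_ever_met']}"
                   f"/{result.daily_goal['n_participants']} "
                   f"({result.daily_goal['pct_ever_met']}%)"]
    report += result.log
    paths["report"].write_text("\n".join(report) + "\n")
    paths["log"].write_text("\n".join(result.log) + "\n")
    return paths
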