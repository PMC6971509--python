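"""Group descriptive comparisons and correlation diagnostics.

Daily activity is heavily right-skewed, so group contrasts use medians with
IQRs and the two-sample Wilcoxon rank-sum (Mann-Whitney) test.  The unit of
analysis defaults to the participant: each participant's valid days are
first collapsed to a per-participant median, and groups of participants are
then compared (``person-day`` mode compares the raw person-days instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

METRICS = {
    "band2_min": "minutes_band2",
    "mvpa_min": "mvpa_min",
    "vpa_min": "vpa_min",
    "total_steps": "total_steps",
}

GROUPINGS = ("sex", "age40", "bmi30")


def participant_level_metric(day_summaries: pd.DataFrame,
                             metric: str = "mvpa_min") -> pd.Series:
    """Median daily value per participant, over that participant's valid days.

    Participants with no valid day are omitted.  Returns a Series indexed by
    participant_id.
    """
    col = METRICS.get(metric, metric)
    valid = day_summaries[day_summaries["valid"]]
    if col not in valid.columns:
        raise KeyError(f"unknown metric {metric!r}")
    return valid.groupby("participant_id", sort=True)[col].median()


def weekly_metric(week_summaries: pd.DataFrame,
                  column: str = "mvpa_min_week") -> pd.Series:
    """Median weekly value per participant over valid weeks."""
    valid = week_summaries[week_summaries["valid_week"]]
    return valid.groupby("participant_id", sort=True)[column].median()


def _group_masks(profiles: pd.DataFrame, grouping: str,
                 ) -> Tuple[pd.Series, str, str]:
    if grouping == "sex":
        return profiles["sex"] == "man", "men", "women"
    if grouping == "age40":
        return profiles["age"] >= 40, "age>=40", "age<40"
    if grouping == "bmi30":
        return profiles["bmi"] >= 30, "obese", "nonobese"
    raise ValueError(f"unknown grouping {grouping!r}")


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U: exact when both groups are small (<=25)
    and tie-free, else the normal approximation with tie correction."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    grouping: str
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    iqr_a: Tuple[float, float]
    median_b: float
    iqr_b: Tuple[float, float]
    statistic: float
    p_value: float


def compare_groups(metric_values: pd.Series, profiles: pd.DataFrame,
                   grouping: str, metric: str = "mvpa_min",
                   ) -> GroupComparison:
    """Median (IQR) per demographic group with a rank-sum p-value.

    ``metric_values`` is a per-participant Series (participant_level_metric
    output) or any participant-indexed values.
    """
    prof = profiles.set_index("participant_id")
    in_a, name_a, name_b = _group_masks(prof, grouping)
    vals = metric_values.dropna()
    ids = vals.index.intersection(prof.index)
    vals = vals.loc[ids]
    a = vals[in_a.reindex(ids).fillna(False)].to_numpy(float)
    b = vals[~in_a.reindex(ids).fillna(False).astype(bool)].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"grouping {grouping!r} yields an empty group")
    stat, p = rank_sum_test(a, b)
    q = lambda x: (float(np.percentile(x, 25)), float(np.percentile(x, 75)))
    return GroupComparison(
        grouping=grouping, metric=metric, group_a=name_a, group_b=name_b,
        n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), iqr_a=q(a),
        median_b=float(np.median(b)), iqr_b=q(b),
        statistic=stat, p_value=p)


def comparison_table(day_summaries: pd.DataFrame, profiles: pd.DataFrame,
                     metrics=("band2_min", "mvpa_min"),
                     groupings=GROUPINGS) -> pd.DataFrame:
    """Cadence-band medians by demographic strata, one row per cell pair."""
    rows = []
    for metric in metrics:
        vals = participant_level_metric(day_summaries, metric)
        for grouping in groupings:
            try:
                c = compare_groups(vals, profiles, grouping, metric)
            except ValueError:
                continue  # one side empty in a small cohort: no contrast
            rows.append({
                "metric": metric, "grouping": grouping,
                "group_a": c.group_a, "n_a": c.n_a,
                "median_a": c.median_a, "iqr_a_low": c.iqr_a[0],
                "iqr_a_high": c.iqr_a[1],
                "group_b": c.group_b, "n_b": c.n_b,
                "median_b": c.median_b, "iqr_b_low": c.iqr_b[0],
                "iqr_b_high": c.iqr_b[1],
                "p_value": c.p_value,
            })
    return pd.DataFrame(rows)


def correlate(x, y, method: str = "rank") -> Tuple[float, float]:
    """Correlation coefficient and p-value.

    ``rank`` (Spearman) suits ordinal pairings such as activity versus the
    IPAQ category; ``linear`` (Pearson) suits the cadence-vs-device MVPA
    comparison.  Zero variance in either vector is an error, not a NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    if method == "rank":
        res = stats.spearmanr(x, y)
    elif method == "linear":
        res = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


IPAQ_ORDER = {"low": 0, "moderate": 1, "high": 2}


def mvpa_vs_ipaq(day_summaries: pd.DataFrame, profiles: pd.DataFrame,
                 ) -> Tuple[float, float]:
    """Spearman correlation of per-participant median daily MVPA with the
    ordinal IPAQ baseline activity category."""
    med = participant_level_metric(day_summaries, "mvpa_min")
    prof = profiles.set_index("participant_id")
    ids = med.index.intersection(prof.index)
    ipaq = prof.loc[ids, "ipaq_category"].map(IPAQ_ORDER)
    return correlate(med.loc[ids].to_numpy(), ipaq.to_numpy(), method="rank")


def classify_ipaq_high(vpa_days_per_week: int, vpa_met_min_per_week: float,
                       mvpa_days_per_week: int, total_met_min_per_week: float,
                       ) -> bool:
    """'High' IPAQ category from raw short-form answers: vigorous activity
    on >=3 days/week at >=1500 MET-min/week, or any-intensity activity on
    >=5 days/week totalling >=3000 MET-min/week."""
    return (vpa_days_per_week >= 3 and vpa_met_min_per_week >= 1500) or \
           (mvpa_days_per_week >= 5 and total_met_min_per_week >= 3000)
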