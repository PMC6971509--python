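"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: linear scans,
closed-form expressions and enumeration, kept simple enough to verify by
eye.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from stepurge import WearConfig


def oracle_nonwear(minutes, cfg=None):
    """Scan every window minute, group missing runs, keep runs >= gap."""
    cfg = cfg or WearConfig()
    present = {ts.hour * 60 + ts.minute
               for ts, hr in zip(minutes["timestamp"], minutes["hr_present"])
               if hr}
    periods, run_start = [], None
    for m in range(cfg.window_start, cfg.window_end + 1):
        missing = m < cfg.window_end and m not in present
        if missing and run_start is None:
            run_start = m
        elif not missing and run_start is not None:
            if m - run_start >= cfg.nonwear_gap_min:
                periods.append((run_start, m))
            run_start = None
    return periods


def oracle_classify(minutes, cfg=None):
    """(wear_minutes, nonwear_periods, valid) by direct rule evaluation."""
    cfg = cfg or WearConfig()
    wear = len({ts.hour * 60 + ts.minute
                for ts, hr in zip(minutes["timestamp"],
                                  minutes["hr_present"])
                if hr and cfg.window_start <= ts.hour * 60 + ts.minute
                < cfg.window_end})
    p = len(oracle_nonwear(minutes, cfg))
    many, low = p >= cfg.max_nonwear_periods, wear < cfg.min_wear_min
    excluded = (many and low) if cfg.exclusion_logic == "both" \
        else (many or low)
    return wear, p, not excluded


def oracle_band_counts(steps, light=60, mvpa=100, vpa=130):
    """Per-minute recount of band minutes, MVPA/VPA and weighted MVPA."""
    counts = [0, 0, 0, 0]
    n_vpa = 0
    for s in steps:
        if s == 0:
            counts[0] += 1
        elif s < light:
            counts[1] += 1
        elif s < mvpa:
            counts[2] += 1
        else:
            counts[3] += 1
            if s >= vpa:
                n_vpa += 1
    return {"bands": counts, "mvpa": counts[3], "vpa": n_vpa,
            "weighted": counts[3] + n_vpa, "total": int(sum(steps))}


def wilson_closed_form(x, n, z=1.959963984540054):
    """Textbook Wilson score interval."""
    p = x / n
    centre = p + z * z / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    denom = 1 + z * z / n
    return (centre - half) / denom, (centre + half) / denom


def ranksum_exact_p(a, b):
    """Two-sided rank-sum p-value by full enumeration of group assignments
    (tie-free samples only)."""
    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n, m = len(a), len(b)
    ws = [sum(combo) for combo in
          itertools.combinations(range(1, n + m + 1), n)]
    mean_w = n * (n + m + 1) / 2
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for w in ws if abs(w - mean_w) >= dev - 1e-9)
    return extreme / len(ws)


def spearman_closed_form(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) for tie-free paired data."""
    n = len(x)
    rx = {v: i + 1 for i, v in enumerate(sorted(x))}
    ry = {v: i + 1 for i, v in enumerate(sorted(y))}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1 - 6 * d2 / (n * (n * n - 1))


def lag1_autocorr(series_list):
    """Pooled lag-1 autocorrelation over per-participant residual series."""
    num = den = 0.0
    for s in series_list:
        s = np.asarray(s, float)
        if len(s) < 2:
            continue
        num += np.sum(s[1:] * s[:-1])
        den += np.sum(s * s)
    return num / den
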