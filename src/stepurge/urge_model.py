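"""Day-level smoking-urge modelling against daily MVPA.

The outcome is mean daily urge (the arithmetic mean of a day's 3-4 Likert
responses); the exposure is daily MVPA reported per 30-minute unit.  The
model is a repeated-measures linear mixed model fitted on its marginal
form: for participant i with valid days t_1 < ... < t_{n_i},

    y_i = X_i beta + e_i,
    Cov(e_i) = sigma^2 [ psi 1 1' + lambda_{g(i)} R_i(rho) ],

where ``psi 1 1'`` is the participant random intercept (variance ratio
psi = sigma_b^2 / sigma^2), R_i is a continuous-time AR(1) correlation with
entries rho^{|t_j - t_k|} in calendar days (gaps from excluded days decay
correlation accordingly), and lambda_g are residual-variance multipliers
over participant groups (quartiles of a pilot fit's per-participant
residual spread), capturing between-participant heteroscedasticity.

Estimation is restricted maximum likelihood with sigma^2 profiled out.
Because the AR(1) process is Markov, each R_i has a tridiagonal inverse:
whitening is a one-pass innovation transform, so one likelihood evaluation
is O(total rows), and the random-intercept term enters by a rank-one
Woodbury update.  Inference on coefficients is Wald with normal quantiles.

Modes: ``ar1-hetero`` (default, full structure), ``ar1-common`` (single
residual scale), ``ri-only`` (random intercept only, rho = 0; in this limit
the fit coincides with an ordinary random-intercept model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_COVARIATES = ("age", "sex_woman", "race_nonwhite",
                      "edu_some_college", "edu_bachelors", "bmi",
                      "cigarettes_per_day", "ipaq_high")


class DegenerateDesignError(ValueError):
    """The design matrix cannot identify the exposure effect."""


def daily_mean_urge(urges: pd.DataFrame) -> pd.DataFrame:
    """Collapse urge responses to person-day means.

    Days with zero responses simply produce no row; they are dropped from
    modelling rather than imputed.
    """
    df = urges.copy()
    df["date"] = df["timestamp"].dt.date
    out = (df.groupby(["participant_id", "date"], sort=True)["urge"]
           .agg(n_responses="size", mean_urge="mean")
           .reset_index())
    out["n_responses"] = out["n_responses"].astype(int)
    out["mean_urge"] = out["mean_urge"].astype(float)
    return out


def build_model_frame(urge_days: pd.DataFrame, day_summaries: pd.DataFrame,
                      profiles: pd.DataFrame,
                      ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Join urge-days to valid wear days and baseline covariates.

    One row per person-day with mean urge, MVPA per 30 min, and the a-priori
    covariates (education as two indicator contrasts against high school or
    less; baseline activity as a high-IPAQ indicator).  Returns the frame
    and a log of how many person-days were dropped and why.
    """
    missing = set(urge_days["participant_id"]) - set(profiles["participant_id"])
    if missing:
        raise ValueError("urge responses for participants without profiles: "
                         f"{sorted(missing)[:5]}")
    days = day_summaries[["participant_id", "date", "valid", "mvpa_min"]]
    merged = urge_days.merge(days, on=["participant_id", "date"], how="left")
    log = {
        "urge_days_total": int(len(merged)),
        "dropped_no_wear_day": int(merged["valid"].isna().sum()),
        "dropped_invalid_day": int((merged["valid"] == False).sum()),  # noqa: E712
    }
    frame = merged[merged["valid"] == True].copy()  # noqa: E712
    log["person_days_modelled"] = int(len(frame))

    prof = profiles.set_index("participant_id")
    pid = frame["participant_id"]
    frame["mvpa30"] = frame["mvpa_min"] / 30.0
    frame["age"] = prof.loc[pid, "age"].to_numpy(float)
    frame["sex_woman"] = (prof.loc[pid, "sex"] == "woman").to_numpy(float)
    frame["race_nonwhite"] = (prof.loc[pid, "race"] == "nonwhite").to_numpy(float)
    edu = prof.loc[pid, "education"].to_numpy()
    frame["edu_some_college"] = (edu == "some-college").astype(float)
    frame["edu_bachelors"] = (edu == "bachelors-or-higher").astype(float)
    frame["bmi"] = prof.loc[pid, "bmi"].to_numpy(float)
    frame["cigarettes_per_day"] = prof.loc[pid, "cigarettes_per_day"].to_numpy(float)
    frame["ipaq_high"] = (prof.loc[pid, "ipaq_category"] == "high").to_numpy(float)
    frame = frame.drop(columns=["valid"])
    return frame.reset_index(drop=True), log


@dataclass
class ModelSpec:
    """Fixed a-priori model specification for the urge fit."""

    exposure: str = "mvpa30"
    covariates: Sequence[str] = DEFAULT_COVARIATES
    mode: str = "ar1-hetero"      # ar1-hetero | ar1-common | ri-only
    n_variance_groups: int = 4
    interactions: Sequence[str] = ()   # moderator columns for exposure x m

    def terms(self) -> list:
        terms = [self.exposure] + list(self.covariates)
        terms += [f"{self.exposure}:{m}" for m in self.interactions]
        return terms


@dataclass
class ModelResult:
    """Coefficients with Wald inference plus covariance-structure estimates."""

    params: pd.DataFrame           # index=term: coef, se, ci_low, ci_high, p
    rho_ar1: float
    sigma2: float                  # base residual variance (group 1)
    intercept_var: float           # participant random-intercept variance
    lambda_groups: Dict[int, float]
    n_participants: int
    n_person_days: int
    converged: bool
    mode: str
    reml_criterion: float
    dropped_terms: Sequence[str] = ()   # aliased covariates removed

    def coef(self, term: str) -> pd.Series:
        return self.params.loc[term]


def _design(frame: pd.DataFrame, spec: ModelSpec,
            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list]:
    df = frame.sort_values(["participant_id", "date"],
                           kind="stable").reset_index(drop=True)
    names = ["intercept"] + spec.terms()
    cols = [np.ones(len(df))]
    for term in spec.terms():
        if ":" in term:
            a, b = term.split(":")
            cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        else:
            cols.append(df[term].to_numpy(float))
    X = np.column_stack(cols)
    y = df["mean_urge"].to_numpy(float)
    pid = df["participant_id"].to_numpy()
    day = pd.to_datetime(df["date"]).map(pd.Timestamp.toordinal).to_numpy(float)
    return y, X, pid, day, names


def _check_design(X: np.ndarray, names: list,
                  exposure: str) -> Tuple[np.ndarray, list, list]:
    """Validate the design; drop aliased covariate columns (QR pivoting).

    A zero-variance or aliased exposure is an error; aliased covariates
    (e.g. an empty education stratum in a small frame) are dropped, as an
    ordinary linear-model fit would, and reported on the result.
    """
    j = names.index(exposure)
    if np.std(X[:, j]) == 0:
        raise DegenerateDesignError(
            f"exposure {exposure!r} has zero variance in the frame")
    # greedy left-to-right selection so earlier terms (intercept, exposure)
    # win over later aliased covariates
    keep: list = []
    basis = np.empty((X.shape[0], 0))
    for k in range(X.shape[1]):
        col = X[:, k]
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(np.linalg.norm(col), 1.0):
            keep.append(k)
            basis = np.column_stack([basis, resid / norm])
    if len(keep) == X.shape[1]:
        return X, names, []
    if j not in keep:
        raise DegenerateDesignError(
            f"exposure {exposure!r} is collinear with the covariates")
    dropped = [names[k] for k in range(X.shape[1]) if k not in keep]
    return X[:, keep], [names[k] for k in keep], dropped


def _variance_groups(y, X, pid_codes, n_pid, n_groups) -> np.ndarray:
    """Assign participants to residual-spread quartile groups via a pilot
    OLS fit with participant-demeaned residuals."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    means = np.bincount(pid_codes, weights=resid, minlength=n_pid) \
        / np.bincount(pid_codes, minlength=n_pid)
    centered = resid - means[pid_codes]
    ss = np.bincount(pid_codes, weights=centered ** 2, minlength=n_pid)
    n_i = np.bincount(pid_codes, minlength=n_pid)
    sd = np.sqrt(ss / np.maximum(n_i - 1, 1))
    sd[n_i < 2] = np.median(sd[n_i >= 2]) if (n_i >= 2).any() else 1.0
    edges = np.quantile(sd, np.linspace(0, 1, n_groups + 1)[1:-1])
    return np.searchsorted(edges, sd, side="right")


def _reml_machinery(y, X, pid, day, group_of_pid):
    """Precompute arrays and return the profiled REML criterion function."""
    n, p = X.shape
    codes, starts = np.unique(pid, return_index=True)
    starts = np.sort(starts)
    first = np.zeros(n, dtype=bool)
    first[starts] = True
    gaps = np.empty(n)
    gaps[0] = 0.0
    gaps[1:] = day[1:] - day[:-1]
    gaps[first] = 0.0
    if (gaps[~first] <= 0).any():
        raise ValueError("duplicate or unsorted days within a participant")
    pid_codes = np.cumsum(first) - 1
    n_pid = len(starts)
    lam_group = group_of_pid  # per-participant group index
    X_prev = np.vstack([np.zeros((1, p)), X[:-1]])
    y_prev = np.concatenate(([0.0], y[:-1]))
    n_per = np.diff(np.append(starts, n))

    def criterion(rho, psi, lam):
        r = np.where(first, 0.0, rho ** gaps)
        denom = 1.0 - r * r
        inv_sq = 1.0 / np.sqrt(denom)
        w = inv_sq / np.sqrt(lam[lam_group][pid_codes])
        yt = (y - r * y_prev) * w
        Xt = (X - r[:, None] * X_prev) * w[:, None]
        ot = (1.0 - r) * w
        A = Xt.T @ Xt
        b = Xt.T @ yt
        yy = yt @ yt
        U = np.add.reduceat(Xt * ot[:, None], starts, axis=0)   # n_pid x p
        s = np.add.reduceat(ot * ot, starts)
        v = np.add.reduceat(ot * yt, starts)
        c = psi / (1.0 + psi * s)
        XtVX = A - U.T @ (c[:, None] * U)
        XtVy = b - U.T @ (c * v)
        yVy = yy - np.sum(c * v * v)
        try:
            L = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            return None
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yVy - beta @ XtVy
        if rss <= 0:
            return None
        sigma2 = rss / (n - p)
        logdet_V = (np.sum(n_per * np.log(lam[lam_group]))
                    + np.sum(np.log(denom))
                    + np.sum(np.log1p(psi * s)))
        logdet_XtVX = 2.0 * np.sum(np.log(np.diag(L)))
        crit = (n - p) * np.log(sigma2) + logdet_V + logdet_XtVX
        return crit, beta, sigma2, XtVX

    return criterion, n, p, n_pid, pid_codes


def fit_urge_model(frame: pd.DataFrame,
                   spec: Optional[ModelSpec] = None,
                   fixed: Optional[Dict[str, float]] = None) -> ModelResult:
    """Fit the adjusted repeated-measures urge model by REML.

    Requires >= 2 participants each contributing >= 2 person-days overall.
    Non-convergence is flagged on the result, never silently ignored;
    an exposure with no variance raises :class:`DegenerateDesignError`.

    ``fixed`` pins the covariance parameters (keys ``rho`` and ``psi``,
    common residual scale) instead of estimating them — a diagnostic tool
    for profiling and for generalized-least-squares comparisons.
    """
    spec = spec or ModelSpec()
    y, X, pid, day, names = _design(frame, spec)
    X, names, dropped_terms = _check_design(X, names, spec.exposure)
    uniq = pd.unique(pid)
    if len(uniq) < 2 or len(y) < len(uniq) + 2:
        raise ValueError("need >= 2 participants with repeated days")

    criterion, n, p, n_pid, pid_codes = _reml_machinery(
        y, X, pid, day, np.zeros(len(uniq), dtype=int))

    if fixed is not None:
        groups = np.zeros(n_pid, dtype=int)
        criterion, n, p, n_pid, pid_codes = _reml_machinery(y, X, pid, day,
                                                            groups)
        rho = float(fixed.get("rho", 0.0))
        psi = float(fixed.get("psi", 1.0))
        out = criterion(rho, psi, np.ones(1))
        if out is None:
            raise np.linalg.LinAlgError("singular covariance at the fixed "
                                        "parameters")
        crit, beta, sigma2, XtVX = out
        cov = sigma2 * np.linalg.inv(XtVX)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        zq = stats.norm.ppf(0.975)
        params = pd.DataFrame({
            "coef": beta, "se": se,
            "ci_low": beta - zq * se, "ci_high": beta + zq * se,
            "p": 2 * stats.norm.sf(np.abs(z)),
        }, index=names)
        return ModelResult(
            params=params, rho_ar1=rho, sigma2=float(sigma2),
            intercept_var=float(psi * sigma2), lambda_groups={0: 1.0},
            n_participants=n_pid, n_person_days=n, converged=True,
            mode=f"{spec.mode} (fixed covariance)",
            reml_criterion=float(crit), dropped_terms=tuple(dropped_terms))

    if spec.mode == "ar1-hetero" and n_pid >= 2 * spec.n_variance_groups:
        groups = _variance_groups(y, X, pid_codes, n_pid,
                                  spec.n_variance_groups)
        _, groups = np.unique(groups, return_inverse=True)  # compact labels
        n_groups = int(groups.max()) + 1
    else:
        groups = np.zeros(n_pid, dtype=int)
        n_groups = 1
    criterion, n, p, n_pid, pid_codes = _reml_machinery(y, X, pid, day, groups)

    mode = spec.mode
    fit_rho = mode in ("ar1-hetero", "ar1-common")

    def unpack(theta):
        k = 0
        if fit_rho:
            rho = 1.0 / (1.0 + np.exp(-theta[k]))
            k += 1
        else:
            rho = 0.0
        psi = np.exp(theta[k])
        k += 1
        lam = np.ones(n_groups)
        if n_groups > 1:
            lam[1:] = np.exp(theta[k:k + n_groups - 1])
        return rho, psi, lam

    def nll(theta):
        if np.any(np.abs(theta) > 30):
            return 1e12
        out = criterion(*unpack(theta))
        if out is None:
            return 1e12
        return out[0]

    x0 = []
    if fit_rho:
        x0.append(np.log(0.25 / 0.75))   # rho start 0.25
    x0.append(0.0)                        # psi start 1
    x0 += [0.0] * (n_groups - 1)
    res = optimize.minimize(nll, np.array(x0), method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-7,
                                     "maxiter": 4000})
    rho, psi, lam = unpack(res.x)
    out = criterion(rho, psi, lam)
    converged = bool(res.success) and out is not None
    if out is None:
        raise np.linalg.LinAlgError("covariance estimate is singular at the "
                                    "returned optimum")
    crit, beta, sigma2, XtVX = out
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    zq = stats.norm.ppf(0.975)
    params = pd.DataFrame({
        "coef": beta, "se": se,
        "ci_low": beta - zq * se, "ci_high": beta + zq * se,
        "p": pvals,
    }, index=names)
    return ModelResult(
        params=params, rho_ar1=float(rho), sigma2=float(sigma2),
        intercept_var=float(psi * sigma2),
        lambda_groups={g: float(l) for g, l in enumerate(lam)},
        n_participants=n_pid, n_person_days=n,
        converged=converged, mode=mode, reml_criterion=float(crit),
        dropped_terms=tuple(dropped_terms))


MODERATORS = ("age40", "sex_woman", "bmi30", "ipaq_high")


def _moderator_column(frame: pd.DataFrame, moderator: str) -> pd.Series:
    if moderator == "age40":
        return (frame["age"] >= 40).astype(float)
    if moderator == "bmi30":
        return (frame["bmi"] >= 30).astype(float)
    if moderator in frame.columns:
        return frame[moderator].astype(float)
    raise KeyError(f"unknown moderator {moderator!r}")


def add_moderator_columns(frame: pd.DataFrame,
                          moderators: Sequence[str] = MODERATORS,
                          ) -> pd.DataFrame:
    """Return a copy of the frame with the binary moderator columns added."""
    out = frame.copy()
    for m in moderators:
        out[m] = _moderator_column(frame, m)
    return out


def interaction_screen(frame: pd.DataFrame,
                       spec: Optional[ModelSpec] = None,
                       moderators: Sequence[str] = MODERATORS,
                       alpha: float = 0.10) -> pd.DataFrame:
    """Screen exposure-by-moderator interactions one at a time.

    Each moderator is added (main effect if not already a covariate, plus
    exposure x moderator product) to the adjusted model; the interaction is
    kept when its Wald p-value is below ``alpha`` (0.10 by convention for
    interaction screens).  Returns a table of p-values and keep flags.
    """
    spec = spec or ModelSpec()
    rows = []
    for m in moderators:
        aug = frame.copy()
        aug[m] = _moderator_column(frame, m)
        covs = list(spec.covariates)
        if m not in covs:
            covs.append(m)
        aug_spec = ModelSpec(exposure=spec.exposure, covariates=covs,
                             mode=spec.mode,
                             n_variance_groups=spec.n_variance_groups,
                             interactions=(m,))
        result = fit_urge_model(aug, aug_spec)
        p = float(result.params.loc[f"{spec.exposure}:{m}", "p"])
        rows.append({"moderator": m, "p_interaction": p,
                     "keep": p < alpha, "converged": result.converged})
    return pd.DataFrame(rows)


def final_model_spec(screen: pd.DataFrame,
                     spec: Optional[ModelSpec] = None) -> ModelSpec:
    """Adjusted-model specification after the interaction screen: only
    moderators whose interaction passed the screen enter as product terms
    (none do when every p-value is at or above the threshold)."""
    spec = spec or ModelSpec()
    kept = tuple(screen.loc[screen["keep"], "moderator"])
    return ModelSpec(exposure=spec.exposure, covariates=spec.covariates,
                     mode=spec.mode,
                     n_variance_groups=spec.n_variance_groups,
                     interactions=kept)


STRATA_RULES = {">10": lambda c: c > 10, ">=15": lambda c: c >= 15,
                ">=20": lambda c: c >= 20}


def stratified_fit(frame: pd.DataFrame,
                   spec: Optional[ModelSpec] = None,
                   rules: Optional[Dict[str, object]] = None,
                   ) -> Dict[str, ModelResult]:
    """Refit the adjusted model within baseline cigarettes-per-day strata.

    Baseline cigarettes/day is dropped as a covariate inside its own
    stratum (it is collinear with stratum membership in narrow strata).
    A stratum with fewer than 2 participants is refused explicitly.
    """
    spec = spec or ModelSpec()
    rules = rules if rules is not None else STRATA_RULES
    out: Dict[str, ModelResult] = {}
    for name, rule in rules.items():
        sub = frame[rule(frame["cigarettes_per_day"])]
        n_pid = sub["participant_id"].nunique()
        if n_pid < 2:
            raise ValueError(
                f"stratum {name!r} has {n_pid} participant(s); at least 2 "
                "are required for a within-stratum fit")
        covs = [c for c in spec.covariates if c != "cigarettes_per_day"]
        sub_spec = ModelSpec(exposure=spec.exposure, covariates=covs,
                             mode=spec.mode,
                             n_variance_groups=spec.n_variance_groups)
        out[name] = fit_urge_model(sub.reset_index(drop=True), sub_spec)
    return out
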