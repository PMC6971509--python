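# Methods

This note records the scientific and numerical choices behind `stepurge`:
the wear/validity rules, the cadence-intensity and adherence definitions,
the repeated-measures urge model and how it is estimated, what the
synthetic-cohort generator does and does not emulate, and the sizes used
in the calibration studies run by the test suite.

## Wear filtering

Wear is assessed inside a civil-time window (default 10:00–22:00,
`WearConfig.window_start/window_end`), because participants are not asked
to wear the tracker overnight. Heart-rate *presence* per minute is the
wear signal; heart-rate values are never used. A minute with no data row
is treated as a minute with missing heart rate — "no row" means "no
data", not "sedentary" — so device-off time is never conflated with
inactivity.

* **Nonwear period**: a maximal run of ≥`nonwear_gap_min` (default 90)
  consecutive in-window minutes without heart rate. Intervals are
  half-open `[start, end)` at minute resolution, so a 90-minute run spans
  exactly 90 minute-slots; runs straddling the window boundary count only
  their in-window portion. An empty day is one full-window period.
* **Day exclusion**: the default logic `both` excludes a day only when it
  has ≥`max_nonwear_periods` (2) nonwear periods **and** wear below
  `min_wear_min` (360 min). The source protocol phrases the rule as a
  conjunction; because that reading is genuinely ambiguous, `either` is
  available in config and both are tested.
* **Week validity**: consecutive 7-day blocks anchored at each
  participant's first recorded date; a week is valid with
  ≥`min_days_per_week` (4) valid days. Trailing blocks shorter than 7
  calendar days are kept and flagged `partial`.
* **Participant inclusion**: recorded span (first to last recorded date,
  inclusive) of at least `min_weeks`·7 days (42). Span, not the count of
  valid weeks, is used: the inclusion rule is a statement about duration
  of recording.

Monotonicity holds by construction: adding heart-rate presence to any
minute can only shorten nonwear runs and raise wear time, so it never
invalidates a valid day.

## Cadence bands and daily summaries

Cadence thresholds are fixed at 60 / 100 / 130 steps per minute
(`BandConfig`); 100 steps/min is the accepted walking cadence for
moderate intensity (≈3 METs) and 130 for vigorous (≈6 METs). No
stride-length adjustment is applied. Banding differs from wear assessment
in two deliberate ways: every *recorded* minute of the day is banded
(activity before 10:00 or after 22:00 still counts), and minutes lacking
heart rate still contribute steps — the validity rules exclude whole
days, never single minutes. MVPA is the unbouted sum of minutes at ≥100;
VPA (≥130) is a subset; `weighted_mvpa_min = mvpa + vpa` implements the
guideline's moderate + 2×vigorous equivalence and is carried through the
weekly totals without further analysis attached.

## Adherence

Weekly totals sum daily minutes over a week's **valid** days only;
invalid weeks keep their totals for inspection but their guideline flags
are null. A participant is adherent when ≥150 MVPA min/week (or ≥75 VPA
min/week) is met on at least `week_fraction` (0.5, boundary inclusive) of
their valid weeks. Participants with zero valid weeks are non-evaluable
and leave the prevalence denominator — this is why the evaluable count
can fall below the retained count. The 95% interval is the Wilson score
interval (Clopper–Pearson available via config); reported percentages are
rounded to the nearest integer, halves away from zero.

## The urge model

Outcome: mean daily urge, the arithmetic mean of the day's answered
prompts (days with no response are dropped, not imputed). Exposure: daily
MVPA divided by 30, so the coefficient reads "urge change per additional
30 MVPA-min/day". Covariates, fixed a priori: age and BMI linear; sex,
race (nonwhite), high-IPAQ indicators; education as two contrasts against
high-school-or-less; baseline cigarettes/day linear.

For participant *i* with valid days *t*₁ < … < *t*ₙ (calendar days),

    y_it = x_it' β + b_i + e_it,   b_i ~ N(0, σ_b²),
    Cov(e_it, e_is) = σ² λ_g(i) ρ^{|t−s|}.

Distances are calendar days, so excluded days decay the AR(1) correlation
as ρ^Δ — craving dynamics run on calendar time, not on observation index.
Heteroscedasticity enters as residual-variance multipliers λ_g over
participant groups; groups are quartiles of per-participant residual SD
from a pilot OLS fit (participant-demeaned residuals). With fewer than
twice `n_variance_groups` participants the model falls back to a common
scale. Three modes exist: `ar1-hetero` (default), `ar1-common` (single
λ), and `ri-only` (ρ = 0), whose estimates coincide with an ordinary
random-intercept mixed model — verified in the tests against an
independent implementation.

**Estimation.** The marginal covariance is σ²(ψ 11' + λ R(ρ)) with
ψ = σ_b²/σ². Because the AR(1) process is Markov, R has a tridiagonal
inverse, so whitening is a one-pass innovation transform (first
observation unchanged, then (z_k − ρ^Δ z_{k−1})/√(1−ρ^{2Δ})); the
rank-one intercept term enters via the Woodbury identity. σ² is profiled
out; the REML criterion is minimized over (logit ρ, log ψ, log λ_g) by
Nelder–Mead (xatol 1e-4, fatol 1e-7), which is robust to the flat ridges
these criteria can have near ρ→0. One criterion evaluation is O(rows),
so a 3 000-person-day fit takes well under a second. Inference is Wald
with normal quantiles.

**Design handling.** A zero-variance or aliased exposure raises a
degenerate-design error. Aliased *covariates* (e.g. an education stratum
empty in a small frame) are dropped by greedy left-to-right selection —
earlier terms win, so the intercept and exposure are always retained —
and reported on the result, as an ordinary linear-model fit would.

**Interaction screen and strata.** Each candidate moderator (age ≥40,
sex, BMI ≥30, high IPAQ) is tested one at a time by adding its main
effect (if absent) and the exposure product; the interaction is kept at
P < .10, the conventional screening level. The final specification
carries only kept products. Sensitivity fits re-estimate the adjusted
model within baseline cigarettes/day strata (>10, ≥15, ≥20), dropping
cigarettes/day as a covariate inside its own stratum to avoid
collinearity in narrow strata; strata with fewer than 2 participants are
refused explicitly.

## Synthetic cohort generator

The generator exists so the pipeline and the model can be verified
without access to raw study data. It emulates:

* **Demographics** drawn to the margins of the target population of
  adult smokers (57% women, 49% nonwhite, BMI classes 23/40/38%,
  education 15/55/30%, IPAQ 11/36/53%, 36% smoking >10/day, all ≥3/day;
  age ~ N(40, 12²) clipped to 18–65).
* **Recording durations** in three strata per 60 enrolled: full 12
  weeks (45), partial 6–12 weeks (8), and short spans (7) that fail the
  6-week inclusion rule — reproducing the enrolment-to-analysis flow.
* **Wear structure**: records run from a drawn wake time (≤10:00) to a
  drawn sleep time (≥22:00), giving the overnight gap; Poisson
  (`wear_gap_rate` = 0.3/day) daytime gaps of 30–180 min; and with
  probability `nonwear_day_prob` = 0.18 a *poor-wear day* (a long morning
  gap plus an early removal for the rest of the day) that fails the day
  rules — chosen so the expected valid-day yield over 12 weeks is about
  69 of 84 days, matching the bookkeeping a real cohort of this kind
  produces.
* **Cadence**: per-day MVPA minutes ~ Gamma(0.9) around a participant
  lognormal scale with male ×1.8 and obese ×0.5 multipliers, normalized
  so the cohort mean is `mean_daily_mvpa_min` (10 min/day) — positively
  skewed, single-digit median, men > women and nonobese > obese, as
  observed in free-living smokers. Minutes are laid down in contiguous
  bouts (brisk 5–20 min, a `vpa_fraction` = 0.25 share at ≥130
  steps/min), light-walking bouts of 3–10 min, scattered incidental
  minutes, and zeros elsewhere, so every band is populated and the
  band-construction invariants (brisk ⇒ ≥100 steps; sedentary ⇒ 0) hold
  exactly.
* **Urge process**: latent mean daily urge
  b₀ᵢ + β·(MVPA_d/30) + AR(1) residual with participant-specific SD
  drawn from `sigma_resid_range` (0.4–0.9 Likert units), intercepts
  N(5, 0.8²); each of 3 prompts is answered with probability 0.92 and
  reports the latent value plus N(0, 0.7²) response noise, rounded and
  clamped to 1–9. Rounding/clamping bias is bounded (<0.1) as long as
  the latent scale stays inside ~[2, 8].
* **Device intensity labels** from noisy per-minute thresholds
  (moderate ≈45, vigorous ≈110 steps/min), emulating an opaque algorithm
  that promotes lower cadences than the 100 steps/min threshold.

One global seed drives a per-participant seed stream, so enlarging the
cohort never perturbs earlier participants, and identical configs give
byte-identical output. The day-level urge layer is exposed directly as
`simulate_model_frame` for calibration studies; it is the same stochastic
process the full generator uses before minute expansion.

**What is not emulated**: device measurement error against a
gold-standard accelerometer, heart-rate values, within-day urge dynamics
(the effect model is day-level by design), covariate effects on urge
(available but zero by default), seasonality, and behavioural feedback
from self-monitoring. Passing tests therefore demonstrate correctness of
the pipeline's rules and the model's frequentist calibration under the
assumed data-generating process — not robustness to the measurement
quirks of any particular device.

## Calibration studies (sizes used)

The acceptance tests run: type-I error of the exposure Wald test over 200
replicates of 50 participants × 8 weeks (band 2–8% at α = .05);
coverage/bias with a true effect of −0.3 over 100 replicates of 50
participants × 12 weeks (coverage ≥90%, mean bias ≤0.05); and the
interaction screen's false-keep rate over 150 replicates of 40
participants × 6 weeks (each moderator within ±3 Monte-Carlo SE of the
10% screening level). Oracle-equivalence checks (nonwear and banding
rules against brute-force linear scans) use 1 000 randomized days each.
These sizes were chosen once as adequate for the stated Monte-Carlo
tolerances.

## Known limitations

* The exclusion logic's conjunction reading means almost no day is
  excluded by small daytime gaps alone; exclusion is driven by
  mostly-off days. Use `either` for a stricter reading.
* The heteroscedasticity grouping (pilot-fit quartiles) is a declared
  modelling choice, not something identifiable from first principles;
  the `ar1-common` mode is the safer default for very small cohorts.
* Wald inference with ~50 participants is adequate for the exposure
  effect (verified by simulation) but small-sample corrections
  (Kenward–Roger-type) are not implemented.
* Cadence is an imprecise intensity surrogate: non-ambulatory activity
  is invisible to it, and thresholds are not stride-adjusted.
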