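# Methods

## The design

The package estimates the effect of a dated, one-shot incentive (an honorary
title awarded to selected physicians of an online health community) on two
monthly service-volume outcomes: home-page views and online consultations.
Treatment is not randomized — awardees are chosen on observable performance —
so the analysis combines two identification strategies:

1. **Selection on observables.** Award assignment is assumed to depend only on
   the five pre-treatment profile covariates (rating score, thank-you letters,
   virtual gifts, contribution score, articles posted). Under this assumption
   the logistic propensity score is a balancing score, and nearest-neighbour
   matching on it yields a control group with comparable covariates and,
   plausibly, parallel outcome trends.
2. **Sharp discontinuity in time.** Within each group, the outcome's monthly
   series is modeled as smooth in the month index except for a possible level
   jump at the award month. The jump is estimated per group and the
   *differential* effect — treated jump minus matched-control jump — removes
   any platform-wide discontinuity common to both arms (a
   difference-in-differences of discontinuities).

The running variable is the integer month index centered at the cutoff
(default month 6 of a 12-month window, the January analogue of a July-June
year); the cutoff month itself is the first post-award month, since awards
conferred mid-month already affect that month's totals. Identification of a
*causal* jump additionally assumes no other group-specific event at the same
month; the lag scan (below) probes the timing assumption rather than testing
it formally.

## Panel convention

Panels are long-format physician-month tables. Month 0 stores each variable's
cumulative state at the window start; months 1–11 store marginal (per-month)
changes, so summing marginals onto the initial state reconstructs cumulative
trajectories (`marginal_changes` / `cumulative_from_marginals` are exact
inverses). Covariate marginals may be negative — ratings decline — so the
[0, 5] rating bound and non-negativity are enforced on the month-0 state and
on outcome marginals only. Estimation uses months 1–11; month 0 supplies the
pre-treatment covariate snapshot for the propensity model and is never an
outcome observation.

## Synthetic data generator

No public panel of this kind exists, so `generate_panel` produces seeded
panels with the design's structure. What it emulates:

- **Covariates**: rating ~ clipped normal (mean 4.5, sd 0.25 on [0, 5]); the
  four count/score covariates ~ rounded log-normals with means ≈ 132, 703,
  79 000, 62 — right-skewed, like real profile statistics.
- **Assignment**: latent score = Σⱼ wⱼ·zⱼ + logistic noise, thresholded, with
  zⱼ the covariate standardized by its theoretical moments. The true
  assignment probability is therefore exactly logistic in the raw covariates
  with slopes wⱼ/sd(xⱼ) (`SynthConfig.implied_logit_slopes`), enabling
  coefficient-recovery tests. Default weights (0.8, 0.6, 0.4, 0.6, 0.3) and
  threshold 2.5 give a marginal award probability near 12% and pre-matching
  imbalance (mean covariate ASD ≈ 0.47) that matching must repair.
- **Exact arm sizes** come from quota (case-control) sampling: candidates are
  drawn and Bernoulli-assigned until both arms are full. This preserves the
  logistic slopes exactly (classic case-control logistic theory) but shifts
  the intercept by the unknown sampling odds, which is why recovery tests
  target slopes, not the intercept.
- **Outcomes**: monthly consultations ~ gamma-Poisson (negative-binomial-type,
  dispersion 0.15) around a linear trend; monthly views ~ mean-corrected
  log-normal noise (sigma 0.5) around a linear trend — both right-skewed.
  Baselines (160 consultations, 170 000 views per month) carry a mean-one
  log-normal physician random intercept (sd 0.3 on the log scale) and a
  multiplicative confounding term exp(0.25·score), so selected physicians are
  genuinely busier — motivating matching and physician-clustered SEs. The
  treated-arm jump (defaults +80 000 views, +20 consultations) is additive in
  the mean from month `cutoff + lag` onward, so both estimators are unbiased
  for it by construction. Slopes default to −3 consultations and −4000 views
  per month (mild decline).
- Defaults of 346 treated vs a pool of 3000 set the study scale.

What it does **not** emulate: seasonality, serially correlated shocks,
platform ranking feedback (views causing future awards), covariate-outcome
dynamics after month 0, or fuzzy/partial compliance. Passing recovery and
calibration tests therefore certifies the estimators under clean
selection-on-observables with additive effects, not robustness to those
violations.

## Estimators and numerical choices

- **Propensity fit**: Newton–Raphson with step-halving (log-likelihood never
  decreases), convergence at gradient max-norm < 1e-8, cap 100 iterations; no
  regularization. Perfect separation is flagged (diverging linear predictor
  with non-vanishing gradient) and the last iterate returned with
  `converged=False`. An optional `log1p` transform of the covariates is off
  by default.
- **Matching**: greedy, treated processed in descending PS (hardest first),
  nearest available control, ties broken by lowest identifier string; no
  caliper by default. Greedy without replacement is deterministic and
  auditable; optimal (assignment-problem) matching is out of scope.
- **ASD** uses n−1 sample variances and the Cohen's-d style denominator
  √((s²_T + s²_C)/2); report summaries average over the five covariates, with
  the PS's own ASD reported separately.
- **Parametric RDD**: OLS with intercept, post indicator, and per-side
  polynomial terms (default order 1). **Nonparametric RDD**: local-linear,
  triangular kernel, 3-month bandwidth by default (months with positive
  kernel weight only; an error reports the minimal feasible bandwidth). The
  two sides are estimated in one fully interacted weighted regression rather
  than two separate side fits: the point estimates are algebraically
  identical, but pooling lets the physician-clustered covariance carry the
  within-physician correlation between the side intercepts. With separate
  side fits and an independence combination of SEs, the physician random
  intercept (present on both sides of the cutoff) makes the jump SE
  conservative — measured empirical size 0.026 at nominal 0.05 over 500 null
  replicates, versus 0.042 for the pooled fit.
- **Uncertainty**: cluster-robust (CR1) sandwich by physician everywhere;
  two-sided normal p-values; no multiplicity adjustment across the four
  group × outcome cells. With all-zero residuals (noiseless fixtures) the SE
  is 0 and the p-value is defined as 0 for a nonzero jump, 1 otherwise.
- **Differential effect**: difference of group jumps; SE = √(SE²_T + SE²_C),
  valid because the groups share no physicians.
- **Lag scan**: re-fits at cutoffs shifted 0..max_lag and returns the full
  profile plus the shift maximizing |estimate|/SE. The profile is returned so
  the selection is auditable; the maximizer is a detection heuristic, not an
  inferential procedure (no selection-adjusted p-value is attached).
- **Pipeline**: validation → propensity → matching → balance → RDD cells →
  differentials → lag scans, with the estimation sample restricted to treated
  plus matched controls; reports are deterministic functions of
  (config, seed).

## Simulation sizes used in tests

Chosen to make each check sharp at modest cost: differential-effect recovery
runs 200 replicate pipelines at the full study scale (346 treated, pool
3000); null calibration uses 500 single-group panels of 800 physicians
(enough clusters for the sandwich variance to settle); balance improvement
uses 50 study-scale replicates; lag recovery uses 200 panels with 346 treated
and pool 346 (the treated arm's distribution does not depend on the pool
quota). The acceptance script averages 60 pipeline replicates and reports the
same quantities.

## Known limitations

- Greedy matching is order-dependent and can be dominated by optimal matching
  when the pool is thin; with the default 8.7:1 pool it balances well (mean
  covariate ASD ≈ 0.056 after matching).
- The nonparametric bandwidth is fixed, not data-driven; with only 11 monthly
  points per physician, optimal-bandwidth machinery offers little.
- The lag scan maximizes a test statistic over shifts without adjusting the
  winning lag's p-value for the search.
- Cluster-robust SEs assume independence across physicians; network spillovers
  between physicians would violate it.
- The normal reference for p-values is asymptotic in the number of
  physicians; below ~50 clusters it can be mildly anti-conservative.
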