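# rddmatch

Causal analysis of a one-shot incentive — an honorary title awarded to
physicians in an online health community — on their monthly service volumes
(home-page views and online consultations), for analysts who have a
physician-month panel and a known award date but no randomized assignment.

The package chains the three standard ingredients of such a design:

1. **Propensity-score estimation.** The probability of receiving the award
   given five pre-treatment profile covariates (rating score, thank-you
   letters, virtual gifts, contribution score, articles posted) is modeled
   logistically, `logit P(D=1 | x) = β₀ + Σⱼ βⱼ xⱼ`, and fitted by an in-repo
   Newton–Raphson maximum-likelihood routine with step-halving and
   perfect-separation diagnostics.
2. **Matching.** Each treated physician is paired with the nearest-PS control
   (greedy, without replacement, optional caliper and 1:N generalization).
   Balance is quantified by the absolute standardized difference
   `ASD = |x̄_T − x̄_C| / √((s²_T + s²_C)/2)`.
3. **Sharp regression discontinuity at the award month.** With running
   variable `t_c = month − cutoff`, the jump `τ = lim_{t↓0} E[y] − lim_{t↑0} E[y]`
   is estimated (a) parametrically, `y = α + τ·D + β·t_c + γ·D·t_c + ε` with
   `D = 1[t_c ≥ 0]` and separate polynomials per side, and (b)
   nonparametrically by triangular-kernel local-linear fits within a 3-month
   bandwidth. Standard errors are cluster-robust by physician; the
   **differential treatment effect** `τ_treated − τ_control` is a
   difference-in-differences of jumps that removes platform-wide shocks. A lag
   scan re-fits the RDD at shifted cutoffs to locate delayed effects.

Because real panels of this kind are proprietary, a first-class synthetic
generator (`SynthConfig` / `generate_panel`) produces seeded panels with the
design's full structure: selection on observables, physician random effects,
skewed count outcomes, and an additive treated-arm jump with optional lag.

## Worked example

`python examples/03_rdd_differential_effect.py` runs the full pipeline on a
simulated study-scale panel (346 treated physicians, control pool of 3000,
true treated-arm jumps of +80 000 monthly views and +20 monthly
consultations) and prints:

```
differential (treated minus control) effects:
  patients parametric    estimate =         18.1  SE =        3.4  p = 9.24e-08
  patients nonparametric estimate =         21.1  SE =        6.9  p = 0.00238
  views    parametric    estimate =      74247.6  SE =    12308.4  p = 1.62e-09
  views    nonparametric estimate =      92988.2  SE =    23869.0  p = 9.79e-05
```

Each line is the treated group's outcome jump at the award month minus the
matched control group's jump, with its combined cluster-robust SE: the
estimates bracket the true simulated effects (80 000 and 20), and the view
effect is far more significant than the consultation effect — the signature
of an incentive that drives attention more than bookings. The other examples
cover panel simulation, propensity fitting + balance checking, and lag
detection; `python examples/04_lag_scan.py` recovers a 2-month delayed jump:

```
  lag 0: jump =    -8468.3  SE =    8498.0  |z| =   1.00
  lag 2: jump =    95048.9  SE =    8733.4  |z| =  10.88
best lag = 2 month(s)
```

A thin CLI wraps the same pipeline: `rddmatch simulate|validate|run|report`
(exit codes 0 success / 1 validation failure / 2 runtime error).

## Layout

- `src/rddmatch/` — `panel` (container, validation, marginal/cumulative
  transforms), `synth` (generator), `propensity`, `matching`, `rdd`
  (estimators, differential effect, lag scan), `pipeline` + `cli`.
- `docs/methods.md` — model assumptions, generator design, numerical choices
  and limitations.
- `examples/` — four narrative scripts, one per capability.
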