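# Methods

## Model

`bivgrowth` fits a bivariate hierarchical linear model to longitudinal
height/weight records of boys aged 2–11, separately for two age windows
(2–5 and 6–11 years). The outcome vector of child *i* at visit *t* is
`y_ti = (log height in metres, log weight in kg)`. With the age covariate
`a_ti` centered at the window start,

    y_ti | η_i  ~  N(η_0i + η_1i · a_ti, diag(σ_eH², σ_eW²))
    η_i         ~  N(β, Ω),     Ω = diag(τ) λ diag(τ)

`η_i = (η_0i, η_1i)` stacks the child's bivariate intercept and slope in
the order (H-int, W-int, H-slope, W-slope); `β` are the population
effects, `Ω` the between-child covariance, `σ_e` the within-child residual
SDs, assumed constant over time and independent across outcomes given
`η_i`. Splitting at age 6 reflects the change in weight-distribution
shape around school start; the windows are closed integer age-year ranges
[2,5] and [6,11], a visit belonging to age-year ⌊age⌋.

Two modelling conventions matter downstream:

* **Height in metres on the log scale.** Then
  `log BMI = log W − 2 log H = lᵀy` with the fixed contrast
  `l = (−2, 1)`, a plain linear functional of the modelled vector, with no
  additive constant. Raw I/O and all reports stay in cm.
* **Centering at the window start.** The window-2 intercept is the child's
  value at age 6, which is exactly the quantity the age-6 handoff rule
  (below) transfers from window 1.

Priors: `β_j ~ N(a_j, b_j)` with `(a_j, b_j)` elicited as the pooled-OLS
estimate and 10× its standard error (weakly informative, data-scaled);
`τ_j ~ half-Cauchy(2.5)`; `λ ~ LKJ(2)` (shape configurable);
`σ_eH, σ_eW ~ inverse-Gamma(0.5, 0.5)` placed on the standard deviations
themselves. The elicitation multiplier, LKJ shape and plug-in estimator
(posterior mean; median selectable) are configurable.

## Posterior computation

Sampling is a self-contained MH-within-Gibbs scheme (`hlm_core.fit`), with
several structure-exploiting updates that standard naive Gibbs lacks and
that are needed for honest convergence on register-like data where most
children have only 2–4 visits:

* `η_i` — exact Gaussian full-conditional draws, batched over children
  (each child needs only a 4×4 Cholesky built from its sufficient
  statistics).
* `β` — collapsed Gibbs: the full conditional with all `η_i` integrated
  out analytically (Woodbury identities reduce everything to 4×4 algebra),
  avoiding the slow random walk that conditioning on weakly identified
  child slopes induces.
* `(τ, λ)` — per-component adaptive random-walk Metropolis on log-scales /
  off-diagonal entries (non-positive-definite proposals rejected), plus an
  ancestral-interweaving update of `τ`: re-expressing `η_i = β + diag(τ)u_i`
  with `u_i` fixed makes `τ` a linear-regression coefficient vector, whose
  conditional Gaussian serves as an independence proposal accepted on the
  prior ratio alone. This breaks the funnel coupling between `τ` and `σ_e`.
* `(τ-slopes, σ_e)` — one additional Metropolis sweep per scan under the
  *marginal* likelihood (η integrated out), because the slope-SD/residual-SD
  pair sits on a near-flat attribution ridge that conditional kernels cross
  slowly.
* `σ_e` — an independence sampler proposing σ² from the likelihood-conjugate
  inverse-Gamma(n/2, RSS/2); the acceptance ratio collapses to a prior
  ratio and is near 1.

All kernels target the exact posterior of the stated model; none is an
approximation. Chains are seeded from `(seed, chain)` sequences and are
bit-reproducible. Defaults: 2 chains, 500 warmup and 1000 stored draws,
`thin = 2` full scans per stored draw; adaptation only during warmup.
Diagnostics (`split_rhat`, `effective_sample_size` with Geyer
initial-monotone truncation) cover `β`, `τ`, `σ_e`; the default pass rule
is max R-hat ≤ 1.01 and min ESS ≥ 400 (configurable; a failed check warns
and returns rather than raising, matching exploratory practice). Constant
chains return R-hat 1 and ESS = total draws by convention, logged.

`m = 1000` per-child effect draws are retained (evenly spaced across
chains) for individual prediction.

## Unconditional distributions

Integrating out `η` gives `E(y) = β₀ + β₁a` and
`Var(y) = diag(σ_e²) + U Ω Uᵀ` with `U = [[1,0,a,0],[0,1,0,a]]`; `y` is
bivariate normal, so natural-scale height, weight and `BMI = exp(lᵀy)` are
exactly lognormal, and their means/SDs follow from
`E exp(z) = exp(μ + v/2)`. The within-sample check table averages these
moments over posterior draws (plug-in evaluation is available and nearly
identical once the posterior concentrates) and sets them against the
empirical per-age-year moments. Posterior columns are evaluated at exact
integer ages while real visits fall after the birthday, so observed means
sit slightly above — by roughly the offset times the growth slope (up to
~2 cm in height at school ages). This gap is a property of the comparison,
not a model defect.

## Prediction approaches

For a target year the package produces per-child posterior-predictive
means `m_i` and variances `v_i` on the log scale:

* **Pred-I** (children with history): for each retained draw `η^(j)` the
  inner expectation `η_0^(j) + η_1^(j)a` is computed in closed form —
  the optional k-draw Monte-Carlo inner loop (default k = 100) only adds
  noise around the same expectation, so closed form is the default —
  and `m_i`/`v_i` are the mean/variance over the `j`s.
* **Pred-P** (any child): one `η` per child per replicate from
  N(β̂, Ω̂) with plug-in posterior means; hyperparameter uncertainty is
  deliberately not propagated.
* **Pred-C**: Pred-I for children in both the contributing and target
  groups, Pred-P for the rest. Routing is a pure function of model
  membership and target age: ages 4–5 use the window-1 model; ages 6–11
  use window 2 directly when the child contributed to it (preferring
  window 2 when both), and otherwise the **age-6 handoff**: the window-1
  posterior value at age 6 becomes the window-2 intercept draw-by-draw,
  and the slope is drawn from the window-2 conditional normal
  (slopes | that intercept) under (β̂, Ω̂) — preserving the
  intercept–slope correlation; a marginal-slope fallback exists for a
  singular intercept block.

Predictions are evaluated at the child's integer target age + 0.5 years by
default (configurable), the expected position of a uniformly timed visit.
Replicated prediction sets re-draw only the population-routed children;
Pred-I components condition on fixed posterior draws and are identical
across replicates (and draw-for-draw equal between Pred-C and standalone
Pred-I).

## Evaluation

* Summary battery: mean, SD (n−1), median, q05/q95 (linear interpolation
  between order statistics), moment skewness `m₃/m₂^1.5` and non-excess
  kurtosis `m₄/m₂²` (normal ⇒ 3); absent with a flag for n < 4 or constant
  samples.
* `wasserstein_1d`: exact W₁ via the integrated absolute difference of
  quantile functions (scipy), arbitrary sizes and weights.
* `wasserstein_2d`: exact W₁ with L1 ground cost between uniform point
  clouds, solved as a minimum-cost perfect matching after least-common-
  multiple weight splitting; instances whose expansion exceeds a cap
  (default 4096) are subsampled with a recorded seed and a logged warning.
  Distances are computed in natural units (cm, kg) without standardisation;
  a standardised option exists but is off by default.
* Per-child Euclidean distances √(Δh² + Δw²) for children with history.
* Replicate aggregation: element-wise means and SDs across prediction
  replicates (SD absent for a single replicate).
* Clinical flags: a predicted-vs-observed median gap is flagged when
  ≥ 2 cm (height), ≥ 1 kg (weight) or ≥ 0.5 kg/m² (BMI). The BMI rule is
  read in the same direction as the others — differences at or above the
  threshold are meaningful — and the threshold is configurable.

## Synthetic cohort generator

Real growth registers are confidential, so `synthetic_cohort` generates
cohorts with the statistical structure the analysis assumes, plus ground
truth for testing:

* Per-child effects drawn from N(β, Ω) per window. By default the two
  windows are **tied**: the window-2 intercept equals the child's window-1
  value at age 6 plus N(0, 0.02²) log-scale jitter, with the slope from the
  window-2 conditional normal — trajectories stay continuous at the
  boundary, mirroring the two-model analysis. `effective_params()` returns
  the exact effective (β, Ω) of the tied process by Gaussian
  marginalisation, so truth-comparison tests remain exact; with
  `tie_windows=False` both windows are independent and nominal.
* Default true parameters are calibrated so the implied unconditional
  moments are realistic for boys of these ages (mean height ≈ 91 cm and
  weight ≈ 13.6 kg at age 2, BMI ≈ 15.9 kg/m² at age 5, weight ≈ 42 kg at
  age 11) with weight log-SD growing with age, hence natural-scale
  skewness increasing with age. The positive weight intercept–slope
  correlation (0.45–0.5) encodes heavier children gaining weight faster.
* Visit process: births uniform over 2010–2017; one candidate visit per
  attainable age-year in 2014–2020 kept with probability 0.7, geometric
  dropout (p = 0.05/year), offsets from the birthday Beta(1, 5) years at
  ages 2–6 (preschool visits cluster near birthdays) and uniform at 7+;
  every child receives one visit in 2021 at the age it attains that year.
  Children flagged non-contributing (probability 766/3535 ≈ 0.217) get no
  2014–2020 visits; flagged contributors are guaranteed ≥ 2 distinct
  age-years, though calendar censoring at the window edges can still
  drop a forced visit, so the realised non-contributing share runs a few
  points above the nominal flag rate.
* Heights are rounded to 1 cm, weights to 0.1 kg, after noise (register
  semantics); ages snap to the day grid so stored dates and outcomes are
  exactly consistent. One pseudo-random stream per (seed, child index)
  makes cohorts reproducible and prefix-stable in n.

What the generator does **not** emulate: secular trends across birth
cohorts, informative missingness (heavier children are not less likely to
be measured), non-lognormal tails in weight, and age-varying covariance.
Consequently, passing tests show the pipeline recovers a correctly
specified data-generating process at register scale — they cannot show
robustness to the misspecifications real registers contain. One visible
consequence: on well-specified synthetic data the population approach
(Pred-P) already reproduces the true marginal shape, so the combined
approach's distribution-level advantage (smaller weight W₁ at older ages)
is a narrow margin decided partly by noise, whereas on real data the
advantage comes from individual parameters capturing skewness the
lognormal population law misses.

## Numerical choices and degenerate inputs

* Ages are exact day counts / 365.25.
* Annual measurement selection keeps, per age-year, the visit closest
  after the preceding birthday, ties broken by earlier visit date (the
  tie-break is this package's choice); the operation is idempotent.
* ω̂ is projected to the nearest positive-definite matrix (eigenvalue
  floor 1e−10) before use; population sampling uses eigendecomposition so
  semi-definite covariances (including exactly zero) are valid.
* Out-of-support parameters give `log_joint = −∞` rather than exceptions.
* Zero-variance samples: SD 0 with flagged, absent skewness/kurtosis;
  W₁ of identical samples is exactly 0.
* Fixture sizes: tiny = 20 children (unit tests), small = 300 (fit and
  recovery tests), medium = 3000 (full-scale checks); the acceptance
  script runs at 3000 children, 2 chains × (400 warmup + 500 stored) × 2
  scans — sizes chosen as the package's standard working scale.

## Known limitations

* The sampler is single-machine and dense; cohorts beyond ~10⁵ children
  would need sparse or distributed refactoring.
* Hyperparameter uncertainty (β, Ω) is not propagated into Pred-P, by
  design; predictive intervals for new children are therefore slightly
  narrow.
* The handoff's slope-conditional is defined under the plug-in (β̂, Ω̂),
  not the full posterior.
* Evaluation treats each age-year independently; no longitudinal
  calibration of predicted trajectories is attempted.
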