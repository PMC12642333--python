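# Methods

## Models

### Hazard models

The minimal development-aging (DA) hazard is a Gompertz law
`h(t) = a·e^{bt}` multiplied by `(1−β)` from a benefit-onset age `d` onwards
(the boundary age `t = d` takes the benefit). `b` is the aging rate — the
exponential slope the hazard would have without developmental benefits — and
is the evolving trait in all simulations.

The human DA (hDA) hazard subtracts two smooth benefit terms from a
Gompertz–Makeham baseline:

```
h(t) = max(0, c + a·e^{bt} − γ(t) − λ(t))
γ(t) = γ_max (1 − 1/(1 + t^{h_γ}))        early benefit; halfway age fixed at 1 y
λ(t) = λ_max (1 − 1/(1 + e^{n(t−k)}))     late benefit; halfway age k
```

The difference can be negative when the benefits exceed the baseline; we
clamp at zero (mortality cannot be negative) before integration and before
the simulator's death trial. This clamp is a modeling choice with real
consequences: it creates a zero-mortality window in early adulthood for large
`γ_max`, which is exactly where the early benefit reverses the sign of its
effect on the selection gradient (below).

The Siler (`a1·e^{−b1 t} + a2 + a3·e^{b3 t}`) and Heligman–Pollard
(`A^{(t+B)^C} + D·e^{−E(ln t − ln F)^2} + G·H^t`) curves are included purely
as descriptive fitting baselines in their standard parameterizations. The
Heligman–Pollard childhood and hump terms are singular at `t = 0`, so age 0
is evaluated at the 0.5-year midpoint; the three-term expression is treated
as a hazard on the log-mortality fitting scale, which is adequate for
fit-quality comparison at the mortality magnitudes involved.

Exponential overflow (extreme `b·t`) raises an error rather than saturating:
a hazard of `e^{700}` is a parameterization bug, not a model state.

### Fertility

Fertility schedules are Brass polynomials
`m_x = v(x−p)(p+w−x)²` on the open window `(p, p+w)`, plus window/constant/
increasing/decreasing schedules for robustness variants. Defaults: `p = 15`,
`w = 35` (human-like onset and span); `v = 1.7257e-5`, frozen so the net
reproduction rate R0 is ≈ 2 under the default hDA life history
(`calibrate_brass_v` recomputes it for any other hazard). These are not
empirical fits; any parameter set can be supplied.

Per-step reproduction probabilities normalize by the maximum over *integer*
ages, `p_x = m_x / max{m_x : x ∈ ℕ}`, so `p_x` attains exactly 1 at the
integer argmax (the continuous argmax of the Brass curve is `p + w/3`).

### Euler–Lotka engine

Fitness is the intrinsic rate of increase `r` solving
`∫_0^∞ e^{−rx} l_x m_x dx = 1` with `l_x = exp(−H(x))`. The integrand
vanishes beyond the fertile window, so truncation at `p+w` is exact. The
age grid uses a 0.1-year step by default. Both the cumulative hazard and the
Euler–Lotka integral use composite Simpson quadrature: trapezoid error at a
0.1-year step (~(b·Δ)²/12 relative) is larger than the closed-form agreement
we require, while Simpson on the same grid matches Gompertz/GMM closed forms
to ~1e-10 relative and the constant-hazard Euler–Lotka root to ~1e-8
(~1e-9 at a 0.05-year step). Since the integrand is smooth except for
isolated kinks (fertility window edges, clamp boundaries), Simpson's local
order reduction there is harmless at these step sizes. The quadratic
interpolant can overshoot on very steep hazard declines, so the cumulative
hazard is forced monotone (`np.maximum.accumulate`) — the true integrand is
nonnegative.

The root is unique (the integral is strictly decreasing in `r`); we bracket
in `[−1, 2]` per year, expand geometrically on failure, and refine with
Brent's method to a residual ≤ 1e-10.

The selection gradient is `σ = [r(0.95·b) − r(b)] / (0.05·b)`: the fitness
gain per unit of aging-rate reduction, from a 5% reduction. Positive σ
favors slower aging. "Decelerates" in the phase diagram means the benefit
*weakens* that selection (`Δr_benefit < Δr_no_benefit`), i.e. the aging rate
evolves to stay higher; "accelerates" is the reverse; the neutral band is
|difference| ≤ 1e-13 (a display threshold, configurable). All gradients are
finite differences; no analytical perturbation theory is used.

### Agent-based simulator

Discrete time, one year per step. Each step applies death → reproduction →
mutation → recruitment:

- **death**: per-agent probability `q = 1 − exp(−[H(x+1) − H(x)])` from the
  agent's own `b` and the shared benefit parameters. The DA increment is the
  exact piecewise-exponential integral split at `d`; the hDA increment is an
  11-point trapezoid on the clamped hazard (the clamp breaks the closed
  form). Survivors age by one year.
- **reproduction**: all agents are shuffled and paired male–female (pairing
  by age rank under `assortative`); both partners must pass independent
  Bernoulli(`p_x`) trials; the offspring receives the parental mean `b` and a
  uniform-random sex. Asexual mode clones each passing agent.
- **mutation**: each offspring mutates with probability 0.02; the mutated `b`
  is redrawn from Normal(`b`, 0.012) and clamped at 0 (negative senescence
  rates are excluded).
- **recruitment**: a uniform random subset of offspring fills the slots freed
  by death, capping the population (default 10,000). Newborns enter at age 0
  and are exposed to neither death nor reproduction in their birth step.

Initialization: ages Normal(20, 10) truncated at 0 and rounded; aging rates
Normal(0.14, 0.005) clamped at 0; sexes uniform. Agents older than the
fertile window are removed by default (they can no longer contribute; the
flag exists because keeping them changes late-time control behavior once
near-immortal non-reproducers accumulate). Replicate streams come from
`SeedSequence([seed, replicate])`, so adding replicates never perturbs
earlier ones; a fixed seed and config reproduce trajectories bit-exactly.

The benefit-vs-control statistic `Δb` is the difference in the
population-mean aging rate at a horizon (default 1,000 steps, 50 replicates)
between arms that differ only in the benefit parameters; positive `Δb` means
the benefit kept aging faster. Arms use independent streams by default
(`paired=True` shares them; with shared streams the reported SE is that of
the paired differences). Extinction truncates a trajectory with a flag
rather than raising.

### Model fitting

`HazardModel.fit()` minimizes `Σ_x [ln h(x;θ) − ln m_x]²` over ages with
`m_x > 0` (zeros and missing cells are dropped, not floored; the count is
reported), with nonnegativity bounds (`b ≤ 1`, `k ≤ 110`, steepness
parameters in (0, 20]) and the model hazard floored at 1e-10 inside the log.
Optimization is bounded trust-region least squares with a deterministic
multi-start: (i) a generic heuristic (Makeham term from the minimum rate,
Gompertz slope from a log-linear regression on ages 40–90, `γ_max` from the
infant rate), (ii) for the hDA model a physiological start that assigns
infant mortality to `c + a` (since `γ(0) = 0`, the intercept must carry it)
and the infant-to-plateau drop to `γ_max`, (iii) the best GMM fit embedded
with zero benefits — this start guarantees `rmse(hDA) ≤ rmse(GMM)` up to
optimizer tolerance, since the hDA family nests GMM — and (iv) ten bounded
random perturbations from a seeded generator. Best final RSS wins.

Goodness of fit is reported on the log scale: `R² = 1 − RSS/TSS`,
`RMSE = √(RSS/n)`, and the Gaussian-RSS information criterion
`AIC = n·ln(RSS/n) + 2K` with `K` = parameter count (no +1 for the variance
term; the form is used only for comparisons within one dataset, where the
constant cancels). A perfect fit reports AIC as NaN.

## Synthetic data

`synth_mortality` emulates the statistical structure the fitting module
assumes about period life tables: a smooth hDA hazard evaluated at integer
ages 0–110 with i.i.d. multiplicative lognormal noise,
`m_x = h(x)·e^{ε_x}`, `ε_x ~ N(0, σ²)`, written in the HMD "Mx 1x1" text
layout (sex columns identical). It does **not** emulate age-correlated
sampling noise (real death counts give binomial noise shrinking with
exposure, largest at the oldest ages), cohort effects, wars/pandemics, or
age heaping — so passing recovery tests show the estimator is correct under
the stated noise model, not that real-data fits carry these error bars.

Two parameter sets ship with the package:

- `DEFAULT_HDA_PARAMS` (fitness module): an illustrative mid-century-UK-like
  set (`c = 0.03`, `a = 1.2e-4`, `b = 0.085`, `γ_max = 0.0295`, `h_γ = 2`,
  `λ_max = 0.001`, `n = 0.2`, `k = 35`) matching the qualitative shape of a
  1950s industrialized-country life table — infant mortality ≈ 0.03/y
  cancelled by the early benefit down to a juvenile plateau ≈ 1e-3/y, and a
  late-benefit halfway age near the mid-30s. It is explicitly not a fit to
  data; landscapes and simulations accept any parameter file.
- `DEFAULT_SYNTH_PARAMS` (io module): the generating truth for recovery
  experiments. It differs only in `λ_max = 0.005` (and slightly in
  `γ_max`, `n`): a recovery experiment is only meaningful when every
  parameter leaves a visible signature in the data, and a late benefit of
  0.001 is below the 5% noise floor, leaving `λ_max` unidentified — which
  would test identifiability, not the fitter.

## Default study conditions and why

- **DA baseline scale `a = 2e-3`.** With the window fertility (ages 15–100)
  and `b₀ ≈ 0.14–0.15`, this puts adult life expectancy near 30 years and
  the phase-diagram crossover between "decelerates" and "accelerates" in the
  20–25 year range — just after the age of first reproduction, with a single
  sign change along `d` and the late-onset (d = 35) benefit on the
  accelerating side. Chosen from the deterministic analysis.
- **Landscape axes.** `b ∈ [0.05, 0.3]`; `λ_max ∈ [0, 0.01]`;
  `γ_max ∈ [0, 0.06]`, i.e. up to ≈ 2× the Makeham term. The γ axis
  deliberately crosses the point where the early benefit zeroes net adult
  mortality: below it, γ_max acts (after its first two years) as a uniform
  hazard shift, which leaves σ exactly invariant in the Euler–Lotka frame up
  to the early-childhood gap (a provable property of the exponential
  discounting: a hazard shift δ at all ages shifts r by δ and cancels), so
  dσ/dγ_max is slightly positive there; above it, enlarging the zero-hazard
  window weakens selection and dσ/dγ_max turns strongly negative. The
  opposing directions (σ rising in λ_max, falling in γ_max) hold at the
  mid-grid reference on these axes.
- **Reduced test scales.** The test suite runs the simulator at populations
  of 500–1,000 for tens to hundreds of steps and the acceptance checks at
  population 1,000 × 300 steps; landscape checks use 20×20 grids at a
  0.1-year integration step. These sizes resolve every qualitative claim the
  tests assert except one: the single-arm `Δb` contrasts of the DA model at
  population 1,000 × 300 steps have true magnitudes of order 5e-5 (measured
  at 400 replicates), below their own replicate noise at small replicate
  counts. The timing contrast (early-benefit arm minus late-benefit arm,
  strong benefit β = 0.5) cancels the shared control and drift terms and is
  the statistic the suite resolves instead.

## Numerical choices

- Simpson quadrature, 0.1-year step (0.05 where a closed-form comparison at
  1e-8 is asserted); cumulative hazards forced monotone.
- Euler–Lotka residual tolerance 1e-10; Brent root refinement at machine
  precision; bracket expansion doubles up to 60 times.
- Least-squares tolerances 1e-14 (ftol/xtol/gtol), `x_scale='jac'` for the
  badly scaled parameter vector (1e-4 … 35).
- Tie-breaks: the benefit boundary `t = d` takes the benefit; window
  fertility includes both endpoints; the Brass window is open.
- Degenerate inputs: all-zero fertility, zero net reproduction, zero
  log-mortality variance, and more data parameters than points raise
  errors; extinction and failed batch fits are flagged, not raised.

## Known limitations

- No cohort-vs-period conversion, no smoothing/graduation, no frailty or
  heterogeneity; the open age class 110+ is treated as exact age 110.
- The simulator evolves only `b`; benefit magnitudes are fixed per run, and
  there are no tradeoffs between aging and other life-history traits.
- Fits are point estimates; no uncertainty quantification.
- The Δb statistic at small population × short horizon is noise-dominated
  (see above); resolving single-arm contrasts at the full default design
  (10,000 agents, 1,000 steps, 50 replicates) is feasible but takes minutes
  per condition.
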