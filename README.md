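# agesim

Tools for studying how the *timing* of developmentally controlled survival
benefits shapes the evolution of aging rates, and for fitting
development-aging hazard models to human-mortality-style life tables.

For most animals, mortality from extrinsic causes (predation, accidents)
falls during development as individuals grow, mature and learn, while
intrinsic senescent mortality rises with age. Whether a developmental
survival benefit *speeds up* or *slows down* the evolution of senescence
turns out to depend on when in life it arrives. `agesim` implements the two
model families used to study this question and the machinery around them:

- **DA model** — Gompertz hazard `h(t) = a·e^{bt}` with a step survival
  benefit: `h(t)·(1−β)` from onset age `d` onwards (β = 0.2 by default).
- **hDA model** — Gompertz–Makeham hazard minus two smooth benefit terms,

  ```
  h(t) = max(0, c + a·e^{bt} − γ(t) − λ(t))
  γ(t) = γ_max · (1 − 1/(1 + t^h))            # early benefit, halfway at 1 y
  λ(t) = λ_max · (1 − 1/(1 + e^{n(t−k)}))     # late benefit, halfway at k
  ```

  which reproduces the rapid infant mortality decline, the early-adult
  plateau, and the senescent rise of human life tables.

On top of the hazard models:

- an **Euler–Lotka fitness engine** (`agesim.fitness`): solves
  `∫ e^{−rx} l_x m_x dx = 1` for the intrinsic rate of increase `r`, computes
  the selection gradient `σ = Δr/Δb` for a 5% reduction in the aging rate,
  phase diagrams over benefit-onset age, fitness landscapes over
  `(b, γ_max)` / `(b, λ_max)`, and benefit-sensitivity maps `Δσ/Δγ_max`,
  `Δσ/Δλ_max`;
- an **agent-based simulator** (`agesim.abm`): a density-regulated population
  (default 10,000 agents) in which each agent carries its own aging rate `b`,
  with per-step death (`q = 1 − e^{−ΔH}`), random male–female pairing,
  Bernoulli reproduction from a normalized fertility schedule, 2% mutation of
  offspring aging rates (SD 0.012), and recruitment of offspring into freed
  slots;
- **model fitting** (`agesim.modelfit`): statsmodels-style
  `HazardModel(...).fit()` returning a results object with parameters, R²,
  RMSE and AIC on log-transformed mortality, for the hDA, Gompertz–Makeham,
  Siler and Heligman–Pollard models;
- **I/O and synthetic data** (`agesim.io_synth`): a reader/writer for the
  Human Mortality Database "Mx 1x1" period layout and a seeded generator of
  synthetic mortality tables (hDA hazard × lognormal noise).

## Worked example

Fit the hDA model to a synthetic mortality table and inspect the fit:

```python
import agesim as ag

from agesim.io_synth import DEFAULT_SYNTH_PARAMS

spec = ag.SynthSpec(params=DEFAULT_SYNTH_PARAMS, noise_sd=0.05, seed=1)
table = ag.synth_mortality(spec)
res = ag.HazardModel.from_table(table, model="hda").fit(seed=0)
print(res.summary())
```

```
Hazard model fit: hda
==============================================
n ages used                                111
ages dropped (mx<=0)                         0
converged                                 True
R^2 (log scale)                       0.999553
RMSE (log scale)                      0.042527
AIC                                  -684.9891
----------------------------------------------
c                                  0.030659246
a                                0.00011671039
b                                  0.085269872
gamma_max                          0.027711192
h_gamma                               1.975291
lambda_max                        0.0048121739
n                                   0.27165796
k                                    34.988201
==============================================
```

The fitted parameters recover the generating truth (c = 0.03, a = 1.2e-4,
b = 0.085, γ_max = 0.027, h_γ = 2, λ_max = 0.005, n = 0.25, k = 35) to within
a few percent despite 5% multiplicative noise; R² is computed on the log
scale, where human mortality spans three orders of magnitude.

Ask the fitness engine whether a 20% survival benefit starting at birth or at
age 35 helps or hinders the evolution of slower aging:

```python
import numpy as np
grid = ag.da_phase_diagram([0.15], np.arange(0, 51, 5.0), beta=0.2)
for d, cls in zip(grid.benefit_values, grid.classification_matrix[0]):
    print(f"d={d:>4.0f}  {cls}")
```

```
d=   0  decelerates
d=   5  decelerates
d=  10  decelerates
d=  15  decelerates
d=  20  decelerates
d=  25  accelerates
d=  30  accelerates
d=  35  accelerates
d=  40  accelerates
d=  45  accelerates
d=  50  accelerates
```

Early benefits weaken the selection for slower aging ("decelerates" its
evolution — aging stays fast); benefits arriving after the crossover near the
age of first reproduction strengthen it.

The same machinery is exposed on the command line:

```
agesim synth --noise-sd 0.05 --seed 1 --out synth_mx.txt
agesim fit --input synth_mx.txt --models hda,gmm,siler,heligman --out fits.csv
agesim phase-diagram --b0-range 0.05:0.3:11 --d-range 0:50:11 --out phase.csv
agesim landscape --vary b,lambda_max --out landscape.csv
agesim simulate --config sim.yaml --seed 1 --out trajectory.csv
```

Every command writes a `<out>.manifest.json` with the resolved configuration
and seed so deterministic outputs can be reproduced bit-exactly.

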