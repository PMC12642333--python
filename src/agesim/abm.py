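"""Agent-based simulation of aging-rate evolution.

Discrete-time, density-regulated population in which each agent carries an
individual Gompertz aging rate ``b`` while all other hazard parameters
(Makeham term, benefit magnitudes and timings) are population-wide constants.
Each time step applies, in order:

1. death      — per-agent Bernoulli trial with q = 1 - exp(-[H(x+1) - H(x)]),
                the integrated hazard over the coming year; survivors age by 1
2. reproduction — random (or age-assortative) male-female pairing; each
                partner passes an independent Bernoulli(p_x) fertility trial;
                a successful couple produces an offspring with the parental
                mean b (asexual mode: per-agent cloning)
3. mutation   — each offspring mutates with a fixed probability, redrawing
                b ~ Normal(b, mutation_sd), clamped at 0
4. fill       — a uniform random subset of offspring fills the slots freed by
                death, capping the population at ``pop_cap``

Newborns enter at age 0 and are not exposed to death or reproduction in their
birth step. Post-reproductive agents are removed by default (they can no
longer contribute offspring; keeping them is a config flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .demography import (
    FertilitySpec,
    fertile_window_end,
    reproduction_probability_table,
)
from .hazards import gamma_benefit, lambda_benefit

__all__ = [
    "SimConfig",
    "Population",
    "Trajectory",
    "DeltaB",
    "init_population",
    "death_step",
    "reproduction_step",
    "mutation_step",
    "fill_step",
    "run",
    "delta_b",
]

_FEMALE, _MALE = 0, 1
_CONTROL_SEED_OFFSET = 1_000_003  # decorrelates control from benefit arm when unpaired

_DA_KEYS = {"a", "beta", "d"}
_HDA_KEYS = {"c", "a", "gamma_max", "h_gamma", "lambda_max", "n", "k"}


def _default_fertility() -> FertilitySpec:
    return FertilitySpec(kind="window", m0=1.0, window=(15.0, 100.0))


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation experiment.

    ``hazard_params`` holds the population-wide hazard constants (everything
    except the evolving aging rate b): for model='da' the keys
    {a, beta, d}; for model='hda' {c, a, gamma_max, h_gamma, lambda_max, n, k}.
    """

    model: str = "da"
    hazard_params: dict = field(default_factory=lambda: {"a": 2e-3, "beta": 0.2, "d": 0.0})
    fertility: FertilitySpec = field(default_factory=_default_fertility)
    pop_cap: int = 10_000
    mutation_rate: float = 0.02
    mutation_sd: float = 0.012
    init_age_mean: float = 20.0
    init_age_sd: float = 10.0
    init_b_mean: float = 0.14
    init_b_sd: float = 0.005
    steps: int = 1000
    replicates: int = 5
    seed: int = 0
    mode: str = "sexual"
    assortative: bool = False
    truncate_post_reproductive: bool = True
    offspring_per_pairing: int = 1

    def __post_init__(self):
        if self.model not in ("da", "hda"):
            raise ValueError(f"model must be 'da' or 'hda', got {self.model!r}")
        required = _DA_KEYS if self.model == "da" else _HDA_KEYS
        missing = required - set(self.hazard_params)
        if missing:
            raise ValueError(f"hazard_params missing {sorted(missing)} for model {self.model!r}")
        if self.pop_cap <= 0:
            raise ValueError("pop_cap must be > 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.mode not in ("sexual", "asexual"):
            raise ValueError(f"mode must be 'sexual' or 'asexual', got {self.mode!r}")
        if self.offspring_per_pairing < 1:
            raise ValueError("offspring_per_pairing must be >= 1")

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimConfig":
        cfg = dict(cfg)
        if "fertility" in cfg and isinstance(cfg["fertility"], dict):
            cfg["fertility"] = FertilitySpec.from_dict(cfg["fertility"])
        return cls(**cfg)


@dataclass
class Population:
    """Evolving agent collection (parallel arrays)."""

    age: np.ndarray  # integer years
    b: np.ndarray  # per-agent aging rate, 1/y
    sex: np.ndarray  # 0 female, 1 male (unused in asexual mode)

    @property
    def n(self) -> int:
        return self.age.size

    def mean_b(self) -> float:
        return float(np.mean(self.b)) if self.n else math.nan


def init_population(cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Draw the initial population: ages N(mean, sd) truncated at 0 and rounded,
    aging rates N(mean, sd) clamped at 0, sexes uniform at random."""
    age = rng.normal(cfg.init_age_mean, cfg.init_age_sd, size=cfg.pop_cap)
    age = np.maximum(np.rint(age), 0).astype(np.int64)
    b = np.maximum(rng.normal(cfg.init_b_mean, cfg.init_b_sd, size=cfg.pop_cap), 0.0)
    sex = rng.integers(0, 2, size=cfg.pop_cap, dtype=np.int8)
    return Population(age=age, b=b, sex=sex)


def _gompertz_integral(a, b, t0, t1):
    """int_t0^t1 a*exp(b*t) dt, elementwise, with the b=0 limit a*(t1-t0)."""
    b = np.asarray(b, dtype=float)
    safe_b = np.where(b == 0.0, 1.0, b)
    expint = (a / safe_b) * (np.exp(safe_b * t1) - np.exp(safe_b * t0))
    return np.where(b == 0.0, a * (t1 - t0), expint)


def _step_delta_H(cfg: SimConfig, age: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Integrated hazard over [x, x+1] for each agent.

    DA: exact piecewise-exponential integral split at the benefit onset d.
    hDA: composite trapezoid on 11 sub-steps (the zero-clamp breaks the
    closed form).
    """
    x = age.astype(float)
    hp = cfg.hazard_params
    if cfg.model == "da":
        a, beta, d = hp["a"], hp["beta"], hp["d"]
        s = np.clip(d, x, x + 1.0)  # benefit applies on [s, x+1]
        return _gompertz_integral(a, b, x, s) + (1.0 - beta) * _gompertz_integral(a, b, s, x + 1.0)
    sub = np.linspace(0.0, 1.0, 11)
    tt = x[:, None] + sub[None, :]
    raw = (
        hp["c"]
        + hp["a"] * np.exp(b[:, None] * tt)
        - gamma_benefit(tt, hp["gamma_max"], hp["h_gamma"])
        - lambda_benefit(tt, hp["lambda_max"], hp["n"], hp["k"])
    )
    return np.trapezoid(np.maximum(raw, 0.0), dx=0.1, axis=1)


def death_step(pop: Population, cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Bernoulli survival trial with q = 1 - exp(-delta_H); survivors age by 1."""
    if pop.n == 0:
        return pop
    q = 1.0 - np.exp(-_step_delta_H(cfg, pop.age, pop.b))
    alive = rng.random(pop.n) >= q
    return Population(age=pop.age[alive] + 1, b=pop.b[alive], sex=pop.sex[alive])


def reproduction_step(
    pop: Population, cfg: SimConfig, rng: np.random.Generator, p_table: np.ndarray
) -> Population:
    """Produce the offspring pool (a Population of age-0 agents).

    Sexual mode pairs shuffled females with shuffled males (age-rank pairing
    when ``assortative``); each partner draws an independent Bernoulli(p_x)
    trial and a successful couple yields ``offspring_per_pairing`` offspring
    with the parental mean b and uniform-random sex.
    """
    empty = Population(
        age=np.empty(0, dtype=np.int64), b=np.empty(0), sex=np.empty(0, dtype=np.int8)
    )
    if pop.n == 0:
        return empty
    p_x = p_table[np.minimum(pop.age, p_table.size - 1)]
    if cfg.mode == "asexual":
        parents = rng.random(pop.n) < p_x
        nb = np.repeat(pop.b[parents], cfg.offspring_per_pairing)
        return Population(
            age=np.zeros(nb.size, dtype=np.int64),
            b=nb,
            sex=rng.integers(0, 2, size=nb.size, dtype=np.int8),
        )
    females = np.flatnonzero(pop.sex == _FEMALE)
    males = np.flatnonzero(pop.sex == _MALE)
    if cfg.assortative:
        females = females[np.argsort(pop.age[females], kind="stable")]
        males = males[np.argsort(pop.age[males], kind="stable")]
    else:
        females = rng.permutation(females)
        males = rng.permutation(males)
    nc = min(females.size, males.size)
    if nc == 0:
        return empty
    f, m = females[:nc], males[:nc]
    ok = (rng.random(nc) < p_x[f]) & (rng.random(nc) < p_x[m])
    nb = np.repeat(0.5 * (pop.b[f[ok]] + pop.b[m[ok]]), cfg.offspring_per_pairing)
    return Population(
        age=np.zeros(nb.size, dtype=np.int64),
        b=nb,
        sex=rng.integers(0, 2, size=nb.size, dtype=np.int8),
    )


def mutation_step(offspring: Population, cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Each offspring mutates with probability ``mutation_rate``: b is redrawn
    from Normal(b, mutation_sd), clamped at 0."""
    if offspring.n == 0 or cfg.mutation_rate == 0.0:
        return offspring
    mutate = rng.random(offspring.n) < cfg.mutation_rate
    b = offspring.b.copy()
    if mutate.any():
        b[mutate] = np.maximum(rng.normal(b[mutate], cfg.mutation_sd), 0.0)
    return Population(age=offspring.age, b=b, sex=offspring.sex)


def fill_step(
    pop: Population, offspring: Population, cfg: SimConfig, rng: np.random.Generator
) -> Population:
    """Fill freed slots with a uniform random subset of offspring (no cap overflow)."""
    free = cfg.pop_cap - pop.n
    k = min(free, offspring.n)
    if k <= 0:
        return pop
    idx = rng.choice(offspring.n, size=k, replace=False)
    return Population(
        age=np.concatenate([pop.age, offspring.age[idx]]),
        b=np.concatenate([pop.b, offspring.b[idx]]),
        sex=np.concatenate([pop.sex, offspring.sex[idx]]),
    )


@dataclass
class Trajectory:
    """Per-replicate mean aging rate and population size, step 0..steps.

    Rows are replicates; NaN past extinction. The pooled 95% CI half-width is
    1.96 * sd(across replicates) / sqrt(replicates).
    """

    mean_b: np.ndarray  # (replicates, steps+1)
    pop_size: np.ndarray  # (replicates, steps+1)
    extinct: np.ndarray  # (replicates,) bool
    extinct_step: np.ndarray  # (replicates,) int, -1 if never

    @property
    def n_replicates(self) -> int:
        return self.mean_b.shape[0]

    def pooled(self) -> pd.DataFrame:
        """Columns step, mean_b, ci_lo, ci_hi, mean_pop_size."""
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(self.mean_b, axis=0)
            sd = np.nanstd(self.mean_b, axis=0, ddof=1) if self.n_replicates > 1 else np.zeros_like(mean)
        half = 1.96 * sd / math.sqrt(self.n_replicates)
        return pd.DataFrame(
            {
                "step": np.arange(self.mean_b.shape[1]),
                "mean_b": mean,
                "ci_lo": mean - half,
                "ci_hi": mean + half,
                "mean_pop_size": np.nanmean(np.where(self.pop_size < 0, np.nan, self.pop_size), axis=0),
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: step, replicate, mean_b, pop_size."""
        reps, steps = self.mean_b.shape
        return pd.DataFrame(
            {
                "step": np.tile(np.arange(steps), reps),
                "replicate": np.repeat(np.arange(reps), steps),
                "mean_b": self.mean_b.ravel(),
                "pop_size": self.pop_size.ravel(),
            }
        )


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # counter-based spawning: adding replicates never perturbs earlier ones
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def run(cfg: SimConfig) -> Trajectory:
    """Run the death -> reproduction -> mutation -> fill loop for each replicate.

    Extinction truncates the trajectory (NaN-padded) and sets the flag; it is
    not an error.
    """
    steps = cfg.steps
    end = fertile_window_end(cfg.fertility)
    table_max = int(min(end, 2000.0)) if math.isfinite(end) else 2000
    p_table = reproduction_probability_table(cfg.fertility, table_max)

    mean_b = np.full((cfg.replicates, steps + 1), np.nan)
    pop_size = np.full((cfg.replicates, steps + 1), -1, dtype=np.int64)
    extinct = np.zeros(cfg.replicates, dtype=bool)
    extinct_step = np.full(cfg.replicates, -1, dtype=np.int64)

    for rep in range(cfg.replicates):
        rng = _replicate_rng(cfg.seed, rep)
        pop = init_population(cfg, rng)
        mean_b[rep, 0] = pop.mean_b()
        pop_size[rep, 0] = pop.n
        for step in range(1, steps + 1):
            pop = death_step(pop, cfg, rng)
            if cfg.truncate_post_reproductive and math.isfinite(end):
                keep = pop.age <= end
                pop = Population(age=pop.age[keep], b=pop.b[keep], sex=pop.sex[keep])
            offspring = reproduction_step(pop, cfg, rng, p_table)
            offspring = mutation_step(offspring, cfg, rng)
            pop = fill_step(pop, offspring, cfg, rng)
            if pop.n == 0:
                extinct[rep] = True
                extinct_step[rep] = step
                pop_size[rep, step] = 0
                break
            mean_b[rep, step] = pop.mean_b()
            pop_size[rep, step] = pop.n
    return Trajectory(mean_b=mean_b, pop_size=pop_size, extinct=extinct, extinct_step=extinct_step)


@dataclass
class DeltaB:
    """Benefit-vs-control contrast of the mean evolved aging rate at a horizon."""

    b0: float
    descriptor: dict
    delta_b: float
    se: float
    n_replicates: int
    horizon: int
    extinction: bool = False

    def to_dict(self) -> dict:
        return {
            "b0": self.b0,
            **{f"benefit_{k}": v for k, v in self.descriptor.items()},
            "delta_b": self.delta_b,
            "se": self.se,
            "n_replicates": self.n_replicates,
            "horizon": self.horizon,
            "extinction": self.extinction,
        }


def delta_b(
    cfg_benefit: SimConfig,
    cfg_control: SimConfig,
    horizon: int = 1000,
    replicates: int = 50,
    paired: bool = False,
) -> DeltaB:
    """Delta_b = mean over replicates of b-bar(horizon)_benefit - b-bar(horizon)_control.

    Positive values mean the survival benefit decelerated the evolution of
    slower aging (the benefit arm kept a higher aging rate). The two arms use
    independent random streams unless ``paired`` (common random numbers). On
    extinction in either arm the contrast is taken at the last step both arms
    reached, with the flag set.
    """
    if cfg_benefit.init_b_mean != cfg_control.init_b_mean:
        raise ValueError("benefit and control configs must share the starting aging rate")
    cfg_b = replace(cfg_benefit, steps=horizon, replicates=replicates)
    ctrl_seed = cfg_control.seed if paired else cfg_control.seed + _CONTROL_SEED_OFFSET
    cfg_c = replace(cfg_control, steps=horizon, replicates=replicates, seed=ctrl_seed)
    traj_b = run(cfg_b)
    traj_c = run(cfg_c)
    extinction = bool(traj_b.extinct.any() or traj_c.extinct.any())
    valid = ~(np.isnan(traj_b.mean_b).any(axis=0) | np.isnan(traj_c.mean_b).any(axis=0))
    last = int(np.flatnonzero(valid).max()) if valid.any() else 0
    xb = traj_b.mean_b[:, last]
    xc = traj_c.mean_b[:, last]
    if paired:
        # common random numbers: replicate i shares its stream across arms,
        # so the contrast variance is that of the paired differences
        se = float(np.std(xb - xc, ddof=1) / math.sqrt(replicates))
    else:
        se = math.sqrt(np.var(xb, ddof=1) / replicates + np.var(xc, ddof=1) / replicates)
    descriptor = {
        k: cfg_benefit.hazard_params[k]
        for k in cfg_benefit.hazard_params
        if cfg_benefit.hazard_params.get(k) != cfg_control.hazard_params.get(k)
    }
    return DeltaB(
        b0=cfg_benefit.init_b_mean,
        descriptor=descriptor,
        delta_b=float(np.mean(xb) - np.mean(xc)),
        se=se,
        n_replicates=replicates,
        horizon=last if extinction else horizon,
        extinction=extinction,
    )
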