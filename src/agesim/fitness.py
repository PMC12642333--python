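"""Deterministic Euler-Lotka fitness engine.

Fitness is the intrinsic rate of population increase r, the root of

    int_0^inf exp(-r*x) * l(x) * m(x) dx = 1

with survivorship l(x) = exp(-H(x)) from a hazard model and fertility m(x)
from a :class:`~agesim.demography.FertilitySpec`. The integral is strictly
decreasing in r, so the root is unique; it is discretized by composite
Simpson quadrature on a fixed age grid and refined by Brent's method.

On top of the solver the module provides the selection gradient on the aging
rate (sigma = dr/db for a 5% reduction in b), phase diagrams over the minimal
development-aging model's (b0, d) plane, fitness landscapes over
(b, gamma_max) or (b, lambda_max), and finite-difference sensitivity maps of
sigma along the benefit axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, simpson
from scipy.optimize import brentq

from .demography import FertilitySpec, fertile_window_end, fertility
from .hazards import DAParams, GMMParams, GompertzParams, HDAParams, HazardSpec

__all__ = [
    "LifeHistory",
    "FitnessResult",
    "FitnessGrid",
    "euler_lotka_r",
    "euler_lotka_r_discrete",
    "selection_gradient",
    "da_phase_diagram",
    "fitness_landscape",
    "benefit_sensitivity",
    "normalize_signed",
    "calibrate_brass_v",
    "DEFAULT_HDA_PARAMS",
]

_RESIDUAL_TOL = 1e-10

# Illustrative UK-1953-like hDA parameter set: infant mortality ~0.03/y that
# the early benefit cancels down to a juvenile plateau ~1e-3/y, Gompertz slope
# 0.085/y, and a late benefit with halfway age 35 y. Used as the default base
# for landscapes and simulations; any fitted parameter set can be substituted.
DEFAULT_HDA_PARAMS = HDAParams(
    c=0.03,
    a=1.2e-4,
    b=0.085,
    gamma_max=0.0295,
    h_gamma=2.0,
    lambda_max=0.001,
    n=0.2,
    k=35.0,
)


@dataclass(frozen=True)
class LifeHistory:
    """Hazard + fertility pair with the integration grid for Euler-Lotka.

    ``max_age`` defaults to the end of the fertile window — truncation there
    is exact because m(x) = 0 beyond it.
    """

    hazard: HazardSpec
    fertility: FertilitySpec
    age_step: float = 0.1
    max_age: float | None = None

    def __post_init__(self):
        if self.age_step <= 0:
            raise ValueError("age_step must be > 0")
        end = fertile_window_end(self.fertility)
        if self.max_age is None:
            if not math.isfinite(end):
                raise ValueError(
                    "fertility schedule is unbounded; supply max_age explicitly"
                )
            object.__setattr__(self, "max_age", float(end))
        elif math.isfinite(end) and self.max_age < end:
            raise ValueError(
                f"max_age {self.max_age} truncates the fertile window (ends {end})"
            )

    def grid(self) -> np.ndarray:
        n = int(np.ceil(self.max_age / self.age_step)) + 1
        return np.linspace(0.0, self.max_age, n)

    def net_maternity(self) -> tuple[np.ndarray, np.ndarray]:
        """Age grid x and the product l(x)*m(x) on it."""
        x = self.grid()
        H = np.maximum.accumulate(
            cumulative_simpson(self.hazard.hazard(x), x=x, initial=0.0)
        )
        lx = np.exp(-H)
        mx = fertility(x, self.fertility)
        return x, lx * mx


@dataclass(frozen=True)
class FitnessResult:
    """Root of the Euler-Lotka equation with its residual."""

    r: float
    converged: bool
    residual: float


def _solve_r(f, bracket=(-1.0, 2.0), max_expand: int = 60) -> FitnessResult:
    """Root of the strictly decreasing function f(r) = integral(r) - 1."""
    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    n = 0
    while flo < 0.0 and n < max_expand:  # root below lo (f decreasing)
        hi, fhi = lo, flo
        lo = lo * 2.0 if lo < 0 else -1.0
        flo = f(lo)
        n += 1
    while fhi > 0.0 and n < max_expand:  # root above hi
        lo, flo = hi, fhi
        hi = hi * 2.0 if hi > 0 else 1.0
        fhi = f(hi)
        n += 1
    if flo < 0.0 or fhi > 0.0:
        raise RuntimeError(
            f"failed to bracket the Euler-Lotka root: f({lo})={flo:.3g}, f({hi})={fhi:.3g}"
        )
    r = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    residual = abs(f(r))
    return FitnessResult(r=float(r), converged=residual <= _RESIDUAL_TOL, residual=residual)


def euler_lotka_r(lh: LifeHistory) -> FitnessResult:
    """Solve the (Simpson-discretized) Euler-Lotka equation for r.

    Raises if the net reproduction rate R0 = int l*m dx is zero (no root).
    """
    x, lxmx = lh.net_maternity()
    r0 = simpson(lxmx, x=x)
    if r0 <= 0.0:
        raise ValueError("net reproduction rate is zero; Euler-Lotka equation has no root")

    def f(r):
        return simpson(np.exp(-r * x) * lxmx, x=x) - 1.0

    return _solve_r(f)


def euler_lotka_r_discrete(ages, net_maternity) -> FitnessResult:
    """Solve sum_x exp(-r*x) * (l_x * m_x) = 1 for a discrete life table.

    ``net_maternity`` holds the products l_x*m_x at the given ages; a single
    entry (point-mass reproduction) has the closed form r = ln(l*m)/x.
    """
    ages = np.asarray(ages, dtype=float)
    lxmx = np.asarray(net_maternity, dtype=float)
    if np.sum(lxmx) <= 0:
        raise ValueError("net reproduction rate is zero; Euler-Lotka equation has no root")

    def f(r):
        return np.sum(np.exp(-r * ages) * lxmx) - 1.0

    return _solve_r(f)


def _with_b(spec: HazardSpec, b: float) -> HazardSpec:
    """Copy of ``spec`` with the Gompertz aging rate replaced."""
    p = spec.params
    if isinstance(p, DAParams):
        new = replace(p, gompertz=replace(p.gompertz, b=b))
    elif isinstance(p, (GompertzParams, GMMParams, HDAParams)):
        new = replace(p, b=b)
    else:
        raise TypeError(f"{type(p).__name__} has no Gompertz aging rate b")
    return replace(spec, params=new)


def _get_b(spec: HazardSpec) -> float:
    p = spec.params
    return p.gompertz.b if isinstance(p, DAParams) else p.b


def selection_gradient(lh: LifeHistory, delta_frac: float = 0.05) -> float:
    """Selection gradient sigma = [r(b*(1-delta)) - r(b)] / (b*delta).

    The fitness change from a 5% (by default) *reduction* in the aging rate b,
    per unit of b; positive sigma favors slower aging.
    """
    b = _get_b(lh.hazard)
    if b <= 0:
        raise ValueError("selection gradient requires aging rate b > 0")
    r1 = euler_lotka_r(lh).r
    lh2 = replace(lh, hazard=_with_b(lh.hazard, b * (1.0 - delta_frac)))
    r2 = euler_lotka_r(lh2).r
    return (r2 - r1) / (b * delta_frac)


@dataclass
class FitnessGrid:
    """Gridded fitness quantities over an aging-rate axis and a second axis.

    ``benefit_values`` holds the second axis (gamma_max, lambda_max, or the
    benefit-onset age d); matrices are indexed [i_b, j_benefit].
    """

    b_values: np.ndarray
    benefit_values: np.ndarray
    benefit_name: str
    r_matrix: np.ndarray | None = None
    sigma_matrix: np.ndarray | None = None
    classification_matrix: np.ndarray | None = None  # strings

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.benefit_values = np.asarray(self.benefit_values, dtype=float)
        shape = (self.b_values.size, self.benefit_values.size)
        for name in ("r_matrix", "sigma_matrix", "classification_matrix"):
            m = getattr(self, name)
            if m is not None and np.shape(m) != shape:
                raise ValueError(f"{name} shape {np.shape(m)} != {shape}")

    def to_dataframe(self) -> pd.DataFrame:
        bb, cc = np.meshgrid(self.b_values, self.benefit_values, indexing="ij")
        out = {"b": bb.ravel(), self.benefit_name: cc.ravel()}
        if self.r_matrix is not None:
            out["r"] = np.asarray(self.r_matrix).ravel()
        if self.sigma_matrix is not None:
            out["sigma"] = np.asarray(self.sigma_matrix).ravel()
        if self.classification_matrix is not None:
            out["class"] = np.asarray(self.classification_matrix).ravel()
        return pd.DataFrame(out)


def da_phase_diagram(
    b0_grid,
    d_grid,
    beta: float = 0.2,
    a: float = 2e-3,
    fert: FertilitySpec | None = None,
    delta_frac: float = 0.05,
    theta: float = 1e-13,
    age_step: float = 0.1,
) -> FitnessGrid:
    """Classify benefit timing as accelerating/decelerating aging evolution.

    For each starting aging rate b0 and benefit-onset age d, compare the
    fitness gain from a 5% reduction in b with (Dr_benefit) and without
    (Dr_no_benefit) the step survival benefit:

    - ``decelerates``  (benefit weakens selection for slower aging, i.e. the
      aging rate evolves faster): Dr_benefit < Dr_no_benefit - theta
    - ``accelerates``: Dr_benefit > Dr_no_benefit + theta
    - ``neutral`` within the band.
    """
    b0_grid = np.asarray(b0_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if b0_grid.size == 0 or d_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if fert is None:
        fert = FertilitySpec(kind="window", m0=1.0, window=(15.0, 100.0))

    def delta_r(b0: float, beta_eff: float, d: float) -> float:
        def r_of(b):
            spec = HazardSpec(
                "da", DAParams(gompertz=GompertzParams(a=a, b=b), beta=beta_eff, d=d)
            )
            return euler_lotka_r(LifeHistory(spec, fert, age_step=age_step)).r

        return r_of(b0 * (1.0 - delta_frac)) - r_of(b0)

    diff = np.empty((b0_grid.size, d_grid.size))
    classes = np.empty(diff.shape, dtype=object)
    for i, b0 in enumerate(b0_grid):
        d_nb = delta_r(b0, 0.0, 0.0)
        for j, d in enumerate(d_grid):
            # beta=0 must reproduce the unperturbed run bit-for-bit: same code path
            d_b = delta_r(b0, beta, d)
            diff[i, j] = d_b - d_nb
            if d_b < d_nb - theta:
                classes[i, j] = "decelerates"
            elif d_b > d_nb + theta:
                classes[i, j] = "accelerates"
            else:
                classes[i, j] = "neutral"
    return FitnessGrid(
        b_values=b0_grid,
        benefit_values=d_grid,
        benefit_name="d",
        sigma_matrix=diff,
        classification_matrix=classes,
    )


def fitness_landscape(
    b_grid,
    benefit_grid,
    which: str,
    base: HDAParams = DEFAULT_HDA_PARAMS,
    fert: FertilitySpec | None = None,
    delta_frac: float = 0.05,
    age_step: float = 0.1,
) -> FitnessGrid:
    """Fitness landscape r(b, benefit) and selection gradients sigma(b, benefit).

    ``which`` selects the benefit axis: 'gamma_max' or 'lambda_max'; all other
    hDA parameters come from ``base``.
    """
    if which not in ("gamma_max", "lambda_max"):
        raise ValueError("which must be 'gamma_max' or 'lambda_max'")
    b_grid = np.asarray(b_grid, dtype=float)
    benefit_grid = np.asarray(benefit_grid, dtype=float)
    if b_grid.size == 0 or benefit_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if fert is None:
        from .demography import DEFAULT_BRASS

        fert = FertilitySpec(kind="brass", brass=DEFAULT_BRASS)

    r_mat = np.empty((b_grid.size, benefit_grid.size))
    sig_mat = np.empty_like(r_mat)
    for j, val in enumerate(benefit_grid):
        params_j = replace(base, **{which: float(val)})
        for i, b in enumerate(b_grid):
            spec = HazardSpec("hda", replace(params_j, b=float(b)))
            lh = LifeHistory(spec, fert, age_step=age_step)
            r_mat[i, j] = euler_lotka_r(lh).r
            spec2 = HazardSpec("hda", replace(params_j, b=float(b) * (1.0 - delta_frac)))
            r2 = euler_lotka_r(LifeHistory(spec2, fert, age_step=age_step)).r
            sig_mat[i, j] = (r2 - r_mat[i, j]) / (float(b) * delta_frac)
    return FitnessGrid(
        b_values=b_grid,
        benefit_values=benefit_grid,
        benefit_name=which,
        r_matrix=r_mat,
        sigma_matrix=sig_mat,
    )


def benefit_sensitivity(grid: FitnessGrid, which: str | None = None) -> np.ndarray:
    """d(sigma)/d(benefit) by central finite differences along the benefit axis."""
    if grid.sigma_matrix is None:
        raise ValueError("grid has no sigma_matrix")
    if grid.benefit_values.size < 2:
        raise ValueError("need >= 2 points along the benefit axis")
    if which is not None and which != grid.benefit_name:
        raise ValueError(f"grid benefit axis is {grid.benefit_name!r}, not {which!r}")
    return np.gradient(grid.sigma_matrix, grid.benefit_values, axis=1)


def normalize_signed(mat: np.ndarray) -> np.ndarray:
    """Display normalization: positives / max positive, negatives / |most negative|."""
    mat = np.asarray(mat, dtype=float)
    out = np.zeros_like(mat)
    pos = mat > 0
    neg = mat < 0
    if pos.any():
        out[pos] = mat[pos] / mat[pos].max()
    if neg.any():
        out[neg] = mat[neg] / abs(mat[neg].min())
    return out


def calibrate_brass_v(
    hazard: HazardSpec | None = None,
    p: float = 15.0,
    w: float = 35.0,
    target_r0: float = 2.0,
    age_step: float = 0.1,
) -> float:
    """Brass scale v such that R0 = int l*m dx hits ``target_r0`` under ``hazard``.

    R0 is linear in v, so a single unit-v integral suffices. Defaults to the
    package's UK-1953-like hDA life history.
    """
    from .demography import BrassParams

    if hazard is None:
        hazard = HazardSpec("hda", DEFAULT_HDA_PARAMS)
    fert = FertilitySpec(kind="brass", brass=BrassParams(v=1.0, p=p, w=w))
    lh = LifeHistory(hazard, fert, age_step=age_step)
    x, lxmx = lh.net_maternity()
    r0_unit = simpson(lxmx, x=x)
    if r0_unit <= 0:
        raise ValueError("life history has zero net reproduction at unit v")
    return float(target_r0 / r0_unit)
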