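"""Mortality-hazard models and derived survival quantities.

The central objects are parameter dataclasses for each hazard law and a
:class:`HazardSpec` wrapper that tags a parameter set with its model name and
evaluates the hazard h(t), the cumulative hazard H(t) and survivorship
l(t) = exp(-H(t)).

Models
------
gompertz   h(t) = a * exp(b*t)
da         Gompertz with a step survival benefit: h(t) * (1 - beta) for t >= d
gmm        Gompertz-Makeham: c + a * exp(b*t)
hda        GMM minus two developmental survival-benefit terms,
           gamma(t) = gamma_max * (1 - 1/(1 + t^h_gamma))       (early, halfway at 1 y)
           lambda(t) = lambda_max * (1 - 1/(1 + exp(n*(t-k))))  (late, halfway at k)
           clamped at zero where the benefits exceed the GMM term
siler      a1*exp(-b1*t) + a2 + a3*exp(b3*t)   (descriptive baseline)
heligman   A^((t+B)^C) + D*exp(-E*(ln t - ln F)^2) + G*H^t   (descriptive baseline)

All evaluators accept scalar or array ages t >= 0 and return nonnegative,
finite hazards; an exponent overflow (extreme b*t) raises ``HazardOverflowError``
rather than silently saturating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Union

import numpy as np
from scipy.integrate import cumulative_simpson

__all__ = [
    "HazardOverflowError",
    "GompertzParams",
    "DAParams",
    "GMMParams",
    "HDAParams",
    "SilerParams",
    "HeligmanParams",
    "HazardSpec",
    "gompertz_hazard",
    "da_hazard",
    "gmm_hazard",
    "gamma_benefit",
    "lambda_benefit",
    "hda_hazard",
    "siler_hazard",
    "heligman_hazard",
    "cumulative_hazard",
    "survivorship",
]

# exp() argument beyond this is treated as a parameter/age error
_EXP_CAP = 700.0


class HazardOverflowError(FloatingPointError):
    """Raised when an exponential term in a hazard would overflow."""


def _safe_exp(z):
    z = np.asarray(z, dtype=float)
    if np.any(z > _EXP_CAP):
        raise HazardOverflowError(
            f"exponent {np.max(z):.3g} exceeds overflow cap {_EXP_CAP:g}; "
            "invalid parameter/age combination"
        )
    return np.exp(z)


def _check_nonneg(obj, *names):
    for name in names:
        v = getattr(obj, name)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz law h(t) = a*exp(b*t): baseline scale ``a`` (1/y) and aging rate ``b`` (1/y)."""

    a: float
    b: float

    def __post_init__(self):
        _check_nonneg(self, "a")
        if not np.isfinite(self.b):
            raise ValueError("b must be finite")


@dataclass(frozen=True)
class DAParams:
    """Gompertz hazard with a step survival benefit of fraction ``beta`` from age ``d`` on."""

    gompertz: GompertzParams
    beta: float = 0.2
    d: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.d < 0:
            raise ValueError(f"d must be >= 0, got {self.d}")

    @property
    def a(self) -> float:
        return self.gompertz.a

    @property
    def b(self) -> float:
        return self.gompertz.b


@dataclass(frozen=True)
class GMMParams:
    """Gompertz-Makeham h(t) = c + a*exp(b*t); ``c`` is the age-independent term."""

    c: float
    a: float
    b: float

    def __post_init__(self):
        _check_nonneg(self, "c", "a")
        if not np.isfinite(self.b):
            raise ValueError("b must be finite")


@dataclass(frozen=True)
class HDAParams:
    """Gompertz-Makeham hazard minus early (gamma) and late (lambda) survival benefits.

    Parameters
    ----------
    c, a, b : GMM parameters (1/y, 1/y, 1/y).
    gamma_max : maximal early-life benefit (1/y); gamma(t) reaches half its
        maximum at age 1 regardless of steepness.
    h_gamma : steepness of the early benefit (dimensionless, > 0).
    lambda_max : maximal late benefit (1/y).
    n : logistic steepness of the late benefit (1/y, > 0).
    k : age at which the late benefit reaches half its maximum (y).
    """

    c: float
    a: float
    b: float
    gamma_max: float = 0.0
    h_gamma: float = 2.0
    lambda_max: float = 0.0
    n: float = 0.3
    k: float = 30.0

    def __post_init__(self):
        _check_nonneg(self, "c", "a", "gamma_max", "lambda_max", "k")
        if not np.isfinite(self.b):
            raise ValueError("b must be finite")
        if self.h_gamma <= 0:
            raise ValueError(f"h_gamma must be > 0, got {self.h_gamma}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")


@dataclass(frozen=True)
class SilerParams:
    """Siler competing-risk hazard a1*exp(-b1*t) + a2 + a3*exp(b3*t), all rates >= 0."""

    a1: float
    b1: float
    a2: float
    a3: float
    b3: float

    def __post_init__(self):
        _check_nonneg(self, "a1", "b1", "a2", "a3", "b3")


@dataclass(frozen=True)
class HeligmanParams:
    """Heligman-Pollard three-term curve A^((t+B)^C) + D*exp(-E*(ln t - ln F)^2) + G*H^t.

    Used only as a descriptive fitting baseline; the childhood and
    accident-hump terms are singular at t = 0, so age 0 is evaluated at the
    0.5-year midpoint.
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    H: float

    def __post_init__(self):
        _check_nonneg(self, "A", "D", "G")
        if self.H <= 0:
            raise ValueError(f"H must be > 0, got {self.H}")


def gompertz_hazard(t, p: GompertzParams):
    """Gompertz hazard a*exp(b*t) at age(s) ``t`` (years)."""
    t = np.asarray(t, dtype=float)
    return p.a * _safe_exp(p.b * t)


def da_hazard(t, p: DAParams):
    """Minimal development-aging hazard: Gompertz scaled by (1-beta) from age d on (inclusive)."""
    t = np.asarray(t, dtype=float)
    h = gompertz_hazard(t, p.gompertz)
    return np.where(t >= p.d, (1.0 - p.beta) * h, h)


def gmm_hazard(t, p: GMMParams):
    """Gompertz-Makeham hazard c + a*exp(b*t)."""
    t = np.asarray(t, dtype=float)
    return p.c + p.a * _safe_exp(p.b * t)


def gamma_benefit(t, gamma_max: float, h_gamma: float):
    """Early-life survival benefit gamma_max*(1 - 1/(1 + t^h_gamma)).

    Monotone non-decreasing from 0 at birth towards ``gamma_max``; equals
    gamma_max/2 at age 1 for every steepness h_gamma > 0.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        th = np.power(t, h_gamma)
    # t^h overflows only for enormous t; the benefit saturates there anyway
    return np.where(np.isinf(th), gamma_max, gamma_max * (1.0 - 1.0 / (1.0 + th)))


def lambda_benefit(t, lambda_max: float, n: float, k: float):
    """Late-life survival benefit: logistic lambda_max*(1 - 1/(1 + exp(n*(t-k)))).

    Halfway at age ``k``; saturates to ``lambda_max`` for n*(t-k) large.
    """
    t = np.asarray(t, dtype=float)
    z = np.clip(n * (t - k), -_EXP_CAP, _EXP_CAP)
    return lambda_max * (1.0 - 1.0 / (1.0 + np.exp(z)))


def hda_hazard(t, p: HDAParams):
    """Human development-aging hazard, clamped at zero.

    h(t) = max(0, c + a*exp(b*t) - gamma(t) - lambda(t)). The clamp encodes
    that developmental benefits cannot drive mortality negative.
    """
    t = np.asarray(t, dtype=float)
    raw = (
        p.c
        + p.a * _safe_exp(p.b * t)
        - gamma_benefit(t, p.gamma_max, p.h_gamma)
        - lambda_benefit(t, p.lambda_max, p.n, p.k)
    )
    return np.maximum(raw, 0.0)


def siler_hazard(t, p: SilerParams):
    """Siler hazard: declining juvenile + constant + rising senescent terms."""
    t = np.asarray(t, dtype=float)
    return p.a1 * np.exp(-p.b1 * t) + p.a2 + p.a3 * _safe_exp(p.b3 * t)


def heligman_hazard(t, p: HeligmanParams):
    """Heligman-Pollard three-term curve, treated as a hazard on the fitting scale.

    Age 0 is evaluated at t = 0.5 (the childhood term A^((t+B)^C) and the
    lognormal accident hump are singular or ill-defined at exactly 0).
    """
    t = np.asarray(t, dtype=float)
    t = np.where(t <= 0.0, 0.5, t)
    child = np.zeros_like(t)
    if p.A > 0:
        child = np.power(p.A, np.power(t + p.B, p.C))
    hump = np.zeros_like(t)
    if p.D > 0 and p.F > 0:
        hump = p.D * np.exp(-p.E * (np.log(t) - np.log(p.F)) ** 2)
    senescent = p.G * np.power(p.H, t)
    if np.any(~np.isfinite(senescent)):
        raise HazardOverflowError("Heligman senescent term overflowed")
    return child + hump + senescent


ParamsType = Union[
    GompertzParams, DAParams, GMMParams, HDAParams, SilerParams, HeligmanParams
]

_EVALUATORS = {
    "gompertz": (GompertzParams, gompertz_hazard),
    "da": (DAParams, da_hazard),
    "gmm": (GMMParams, gmm_hazard),
    "hda": (HDAParams, hda_hazard),
    "siler": (SilerParams, siler_hazard),
    "heligman": (HeligmanParams, heligman_hazard),
}


@dataclass(frozen=True)
class HazardSpec:
    """A hazard model tag paired with its parameter set.

    ``model_tag`` is one of {gompertz, da, gmm, hda, siler, heligman}.
    """

    model_tag: str
    params: ParamsType
    integration_step: float = 0.1

    def __post_init__(self):
        if self.model_tag not in _EVALUATORS:
            raise ValueError(
                f"unknown model_tag {self.model_tag!r}; expected one of {sorted(_EVALUATORS)}"
            )
        expected, _ = _EVALUATORS[self.model_tag]
        if not isinstance(self.params, expected):
            raise TypeError(
                f"model_tag {self.model_tag!r} expects {expected.__name__}, "
                f"got {type(self.params).__name__}"
            )
        if self.integration_step <= 0 or self.integration_step > 0.1:
            raise ValueError("integration_step must be in (0, 0.1]")

    def hazard(self, t):
        """Evaluate h(t) at scalar or array ages."""
        _, fn = _EVALUATORS[self.model_tag]
        return fn(t, self.params)

    @classmethod
    def from_dict(cls, cfg: dict) -> "HazardSpec":
        """Build from a config mapping {'model': tag, 'params': {...}}."""
        tag = cfg["model"]
        if tag not in _EVALUATORS:
            raise ValueError(f"unknown model {tag!r}")
        ptype, _ = _EVALUATORS[tag]
        if tag == "da":
            raw = dict(cfg["params"])
            gomp = GompertzParams(a=raw.pop("a"), b=raw.pop("b"))
            params = DAParams(gompertz=gomp, **raw)
        else:
            params = ptype(**cfg["params"])
        return cls(model_tag=tag, params=params)

    def to_dict(self) -> dict:
        if self.model_tag == "da":
            p: DAParams = self.params
            raw = {"a": p.a, "b": p.b, "beta": p.beta, "d": p.d}
        else:
            raw = {f.name: getattr(self.params, f.name) for f in fields(self.params)}
        return {"model": self.model_tag, "params": raw}


def cumulative_hazard(spec: HazardSpec, t, step: float | None = None):
    """Cumulative hazard H(t) = int_0^t h(u) du by composite Simpson quadrature.

    ``t`` may be scalar or array; the integrand is the clamped hazard, so H is
    monotone non-decreasing with H(0) = 0. The grid step defaults to the
    spec's ``integration_step`` (0.1 y); Simpson's rule on that grid matches
    the Gompertz/GMM closed forms to ~1e-10 relative.
    """
    step = spec.integration_step if step is None else step
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("ages must be >= 0")
    tmax = float(t_arr.max()) if t_arr.size else 0.0
    if tmax == 0.0:
        out = np.zeros_like(t_arr)
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out
    n = int(np.ceil(tmax / step)) + 1
    grid = np.linspace(0.0, tmax, n)
    H = cumulative_simpson(spec.hazard(grid), x=grid, initial=0.0)
    # Simpson's quadratic interpolant can overshoot on very steep declines;
    # the true integrand is >= 0, so H is monotone by construction
    H = np.maximum.accumulate(H)
    out = np.interp(t_arr, grid, H)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def survivorship(spec: HazardSpec, x, step: float | None = None):
    """Survivorship l(x) = exp(-H(x)); l(0) = 1 and non-increasing in x."""
    return np.exp(-cumulative_hazard(spec, x, step=step))
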