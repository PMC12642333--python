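"""Fertility schedules and per-step reproduction probabilities.

The same :class:`FertilitySpec` feeds both the deterministic Euler-Lotka
engine (as a rate m_x of offspring per year) and the agent-based simulator
(as a per-step reproduction probability p_x = m_x / max over integer ages).

Kinds
-----
brass       m_x = v*(x-p)*(p+w-x)^2 on the open fertile window (p, p+w)
window      m_x = m0 on the closed interval [min_age, max_age]
constant    m_x = m0 at every age (optionally clipped to a window)
increasing  m_x = m0 + slope*x (requires a window for normalization)
decreasing  m_x = max(0, m0 - slope*x)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BrassParams",
    "FertilitySpec",
    "fertility",
    "reproduction_probability",
    "reproduction_probability_table",
    "fertile_window_end",
    "DEFAULT_BRASS",
]

# Integer-age cap when enumerating the normalizing maximum for schedules
# without a natural upper bound.
_ENUM_CAP = 1000


@dataclass(frozen=True)
class BrassParams:
    """Brass polynomial fertility m_x = v*(x-p)*(p+w-x)^2.

    ``v`` scales the schedule (offspring * y^-3), ``p`` is the age of fertility
    onset and ``w`` the width of the fertile window (both years). The
    continuous maximum sits at x = p + w/3.
    """

    v: float
    p: float
    w: float

    def __post_init__(self):
        if self.v < 0:
            raise ValueError(f"v must be >= 0, got {self.v}")
        if self.p < 0:
            raise ValueError(f"p must be >= 0, got {self.p}")
        if self.w <= 0:
            raise ValueError(f"w must be > 0, got {self.w}")


@dataclass(frozen=True)
class FertilitySpec:
    """A tagged fertility schedule.

    For ``kind='brass'`` supply ``brass``; the other kinds use ``m0``,
    ``slope`` and (where needed) ``window = (min_age, max_age)``.
    """

    kind: str = "brass"
    brass: BrassParams | None = None
    m0: float = 1.0
    slope: float = 0.1
    window: tuple[float, float] | None = None

    def __post_init__(self):
        kinds = {"brass", "constant", "increasing", "decreasing", "window"}
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {sorted(kinds)}, got {self.kind!r}")
        if self.kind == "brass" and self.brass is None:
            raise ValueError("kind='brass' requires brass parameters")
        if self.kind == "window" and self.window is None:
            raise ValueError("kind='window' requires window=(min_age, max_age)")
        if self.window is not None and self.window[1] <= self.window[0]:
            raise ValueError(f"window must satisfy min_age < max_age, got {self.window}")
        if self.m0 < 0:
            raise ValueError(f"m0 must be >= 0, got {self.m0}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "FertilitySpec":
        """Build from a config mapping, e.g. {'kind': 'brass', 'v': .., 'p': 15, 'w': 35}."""
        cfg = dict(cfg)
        kind = cfg.pop("kind")
        if kind == "brass":
            return cls(kind="brass", brass=BrassParams(v=cfg["v"], p=cfg["p"], w=cfg["w"]))
        window = cfg.get("window")
        return cls(
            kind=kind,
            m0=cfg.get("m0", 1.0),
            slope=cfg.get("slope", 0.1),
            window=tuple(window) if window is not None else None,
        )


def fertility(x, spec: FertilitySpec):
    """Fertility rate m_x (offspring per time unit) at age(s) ``x``."""
    x = np.asarray(x, dtype=float)
    if spec.kind == "brass":
        b = spec.brass
        inside = (x > b.p) & (x < b.p + b.w)
        m = np.where(inside, b.v * (x - b.p) * (b.p + b.w - x) ** 2, 0.0)
    elif spec.kind == "window":
        lo, hi = spec.window
        m = np.where((x >= lo) & (x <= hi), spec.m0, 0.0)
    elif spec.kind == "constant":
        m = np.full_like(x, spec.m0)
    elif spec.kind == "increasing":
        m = spec.m0 + spec.slope * x
    else:  # decreasing, floored at zero
        m = np.maximum(spec.m0 - spec.slope * x, 0.0)
    if spec.kind in ("constant", "increasing") and spec.window is not None:
        lo, hi = spec.window
        m = np.where((x >= lo) & (x <= hi), m, 0.0)
    return m


def fertile_window_end(spec: FertilitySpec) -> float:
    """Last age with possible reproduction (p+w for Brass); +inf disables truncation."""
    if spec.kind == "brass":
        return spec.brass.p + spec.brass.w
    if spec.kind == "window":
        return float(spec.window[1])
    if spec.kind == "decreasing":
        end = spec.m0 / spec.slope if spec.slope > 0 else math.inf
        if spec.window is not None:
            end = min(end, spec.window[1])
        return end
    if spec.window is not None:
        return float(spec.window[1])
    return math.inf


def _max_over_integer_ages(spec: FertilitySpec) -> float:
    end = fertile_window_end(spec)
    if not math.isfinite(end):
        if spec.kind == "constant":
            return spec.m0
        if spec.kind == "increasing":
            raise ValueError(
                "increasing fertility without a window has no finite maximum; set window="
            )
        end = _ENUM_CAP
    ages = np.arange(0, int(math.floor(end)) + 1)
    return float(np.max(fertility(ages, spec)))


def reproduction_probability(x, spec: FertilitySpec):
    """Per-step reproduction probability p_x = m_x / max{m_x : x in N}.

    The normalizing maximum is taken over integer ages, so p_x attains exactly
    1 at the integer argmax. Raises if the schedule is identically zero.
    """
    mmax = _max_over_integer_ages(spec)
    if mmax <= 0:
        raise ValueError("fertility schedule is zero at all integer ages; no reproduction possible")
    return fertility(x, spec) / mmax


def reproduction_probability_table(spec: FertilitySpec, max_age: int) -> np.ndarray:
    """p_x at integer ages 0..max_age inclusive (lookup table for the simulator)."""
    return np.asarray(reproduction_probability(np.arange(max_age + 1), spec), dtype=float)


# Default human-like Brass schedule: onset 15 y, 35 y fertile window.  The
# scale v is frozen so the net reproduction rate R0 under the package's
# default UK-1953-like hDA life history is ~2 (see agesim.fitness.calibrate_brass_v).
DEFAULT_BRASS = BrassParams(v=1.7256616099929278e-05, p=15.0, w=35.0)
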