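"""Least-squares fitting of hazard models to per-age mortality rates.

The interface follows the Model/Results convention: a :class:`HazardModel`
is built from data (ages and central death rates mx, or a
:class:`~agesim.io_synth.MortalityTable`), and ``fit()`` returns a
:class:`HazardFitResults` carrying the fitted parameters, goodness-of-fit
metrics on the log scale (R^2, RMSE, AIC) and a ``summary()`` table.

Fitting minimizes sum_x [ln h(x; theta) - ln mx]^2 over ages with mx > 0
(zeros and missing cells are dropped), with nonnegativity bounds and a
deterministic multi-start: a heuristic start, an embedded best-GMM start for
the hDA model, and bounded random perturbations; the best final RSS wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .hazards import (
    GMMParams,
    GompertzParams,
    HDAParams,
    HazardSpec,
    HeligmanParams,
    SilerParams,
)
from .io_synth import MortalityTable

__all__ = [
    "HazardModel",
    "HazardFitResults",
    "FitResult",
    "FitBatch",
    "fit_model",
    "goodness_metrics",
    "fit_batch",
]

_HAZARD_FLOOR = 1e-10

_PARAM_NAMES = {
    "gompertz": ["a", "b"],
    "gmm": ["c", "a", "b"],
    "hda": ["c", "a", "b", "gamma_max", "h_gamma", "lambda_max", "n", "k"],
    "siler": ["a1", "b1", "a2", "a3", "b3"],
    "heligman": ["A", "B", "C", "D", "E", "F", "G", "H"],
}

_PARAM_TYPES = {
    "gompertz": GompertzParams,
    "gmm": GMMParams,
    "hda": HDAParams,
    "siler": SilerParams,
    "heligman": HeligmanParams,
}

# (lower, upper) per parameter; shared nonnegativity with model-specific caps
_BOUNDS = {
    "gompertz": ([0.0, 0.0], [np.inf, 1.0]),
    "gmm": ([0.0, 0.0, 0.0], [np.inf, np.inf, 1.0]),
    "hda": (
        [0.0, 0.0, 0.0, 0.0, 1e-6, 0.0, 1e-6, 0.0],
        [np.inf, np.inf, 1.0, np.inf, 20.0, np.inf, 20.0, 110.0],
    ),
    "siler": ([0.0] * 5, [np.inf, 20.0, np.inf, np.inf, 1.0]),
    "heligman": (
        [0.0, 0.0, 0.0, 0.0, 0.0, 1e-3, 0.0, 1.0 + 1e-9],
        [0.999, 10.0, 10.0, 1.0, 50.0, 110.0, 1.0, 5.0],
    ),
}


def goodness_metrics(observed_log, predicted_log, n_params: int):
    """R^2, RMSE and AIC on the log-mortality scale.

    AIC uses the Gaussian-RSS form n*ln(RSS/n) + 2K with K = ``n_params``;
    a perfect fit (RSS = 0) reports AIC as NaN. Raises on zero total variance
    or when n_points <= n_params.
    """
    y = np.asarray(observed_log, dtype=float)
    yhat = np.asarray(predicted_log, dtype=float)
    n = y.size
    if n <= n_params:
        raise ValueError(f"need more data points ({n}) than parameters ({n_params})")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("observed log-mortality has zero variance; R^2 undefined")
    rss = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - rss / tss
    rmse = math.sqrt(rss / n)
    aic = math.nan if rss == 0.0 else n * math.log(rss / n) + 2 * n_params
    return r2, rmse, aic


class HazardModel:
    """A hazard law to be fitted to per-age central death rates.

    Ages with non-finite or non-positive mx are dropped before fitting (the
    log transform requires mx > 0); ``max_age`` optionally trims noisy old
    ages. ``model`` is one of {gompertz, gmm, hda, siler, heligman}.
    """

    def __init__(self, ages, mx, model: str = "hda", max_age: float | None = None):
        if model not in _PARAM_NAMES:
            raise ValueError(f"unknown model {model!r}; expected one of {sorted(_PARAM_NAMES)}")
        ages = np.asarray(ages, dtype=float)
        mx = np.asarray(mx, dtype=float)
        if ages.shape != mx.shape:
            raise ValueError("ages and mx must have the same length")
        keep = np.isfinite(mx) & (mx > 0)
        if max_age is not None:
            keep &= ages <= max_age
        self.model = model
        self.ages = ages[keep]
        self.mx = mx[keep]
        self.n_dropped = int(np.sum(~keep))
        k = len(_PARAM_NAMES[model])
        if self.ages.size < k + 2:
            raise ValueError(
                f"insufficient data: {self.ages.size} usable ages for {k} parameters"
            )
        self._log_mx = np.log(self.mx)

    @classmethod
    def from_table(
        cls, table: MortalityTable, sex: str = "total", model: str = "hda",
        max_age: float | None = None,
    ) -> "HazardModel":
        return cls(table.ages, table.mx(sex), model=model, max_age=max_age)

    # -- parameter plumbing -------------------------------------------------
    def _to_params(self, theta: np.ndarray):
        names = _PARAM_NAMES[self.model]
        return _PARAM_TYPES[self.model](**dict(zip(names, map(float, theta))))

    def _predict_log(self, theta: np.ndarray) -> np.ndarray:
        spec = HazardSpec(self.model, self._to_params(theta))
        return np.log(np.maximum(spec.hazard(self.ages), _HAZARD_FLOOR))

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self._predict_log(theta) - self._log_mx

    # -- starting points ----------------------------------------------------
    def _old_age_regression(self) -> tuple[float, float]:
        """Slope/intercept of ln mx over the senescent range (ages 40-90)."""
        sel = (self.ages >= 40) & (self.ages <= 90)
        if np.sum(sel) < 3:
            sel = self.ages >= np.median(self.ages)
        coef = np.polyfit(self.ages[sel], self._log_mx[sel], 1)
        b = float(np.clip(coef[0], 1e-4, 0.99))
        a = float(np.clip(np.exp(coef[1]), 1e-12, None))
        return a, b

    def _heuristic_starts(self) -> list[np.ndarray]:
        a, b = self._old_age_regression()
        mx0 = float(self.mx[np.argmin(self.ages)])
        mx_min = float(self.mx.min())
        if self.model == "gompertz":
            return [np.array([a, b])]
        if self.model == "gmm":
            return [np.array([mx_min, a, b])]
        if self.model == "siler":
            a1 = max(mx0 - mx_min - a, 1e-6)
            return [np.array([a1, 1.0, mx_min, a, b])]
        if self.model == "heligman":
            A = float(np.clip(mx0, 1e-6, 0.5))
            return [
                np.array([A, 0.1, 0.1, 1e-4, 10.0, 20.0, max(a, 1e-12), math.exp(b)])
            ]
        # hda: the generic start plus a physiological one -- h(0) = c + a must
        # carry infant mortality since gamma(0) = 0
        generic = np.array(
            [mx_min, a, b, mx0, 2.0, 0.1 * mx0, 0.3, 30.0]
        )
        gamma0 = max(mx0 - mx_min, 1e-6)
        physio = np.array(
            [max(mx0 - a, 1e-6), a, b, gamma0, 2.0, max(0.1 * gamma0, 1e-6), 0.3, 30.0]
        )
        return [generic, physio]

    def _embedded_gmm_start(self, seed: int) -> np.ndarray | None:
        if self.model != "hda":
            return None
        gmm_fit = HazardModel(self.ages, self.mx, model="gmm").fit(seed=seed, n_restarts=3)
        c, a, b = gmm_fit.params_array
        return np.array([c, a, max(b, 1e-4), 0.0, 2.0, 0.0, 0.3, 30.0])

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        init=None,
        bounds=None,
        n_restarts: int = 10,
        seed: int = 0,
    ) -> "HazardFitResults":
        """Bounded least squares on log mortality with deterministic multi-start.

        ``init`` (parameter vector or dataclass) adds a user start;
        ``bounds`` overrides the default (lower, upper) arrays;
        ``n_restarts`` random perturbations of the best heuristic start.
        """
        lo, hi = bounds if bounds is not None else _BOUNDS[self.model]
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        starts = self._heuristic_starts()
        emb = self._embedded_gmm_start(seed)
        if emb is not None:
            starts.append(emb)
        if init is not None:
            if hasattr(init, "__dataclass_fields__"):
                init = [getattr(init, n) for n in _PARAM_NAMES[self.model]]
            starts.insert(0, np.asarray(init, dtype=float))

        rng = np.random.default_rng(seed)
        base = starts[0]
        for _ in range(n_restarts):
            pert = base * np.exp(rng.normal(0.0, 0.5, size=base.size))
            starts.append(pert)

        best = None
        any_ok = False
        for x0 in starts:
            x0 = np.clip(x0, lo + 1e-15, np.where(np.isfinite(hi), hi - 1e-15, x0))
            x0 = np.maximum(x0, lo)
            try:
                sol = least_squares(
                    self._residuals,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    x_scale="jac",
                    ftol=1e-14,
                    xtol=1e-14,
                    gtol=1e-14,
                    max_nfev=4000,
                )
            except Exception:
                continue
            any_ok = True
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol)
        if best is None:
            return HazardFitResults(
                model=self, params=None, rss=math.nan, converged=False,
                r2=math.nan, rmse=math.nan, aic=math.nan,
            )
        rss, sol = best
        k = len(_PARAM_NAMES[self.model])
        r2, rmse, aic = goodness_metrics(self._log_mx, self._log_mx + sol.fun, k)
        return HazardFitResults(
            model=self,
            params=self._to_params(sol.x),
            rss=rss,
            converged=bool(any_ok and sol.success),
            r2=r2,
            rmse=rmse,
            aic=aic,
        )


@dataclass
class HazardFitResults:
    """Fitted parameters with goodness-of-fit metrics (log-mortality scale)."""

    model: HazardModel
    params: object | None
    rss: float
    converged: bool
    r2: float
    rmse: float
    aic: float

    @property
    def model_tag(self) -> str:
        return self.model.model

    @property
    def n_points(self) -> int:
        return int(self.model.ages.size)

    @property
    def param_names(self) -> list[str]:
        return list(_PARAM_NAMES[self.model.model])

    @property
    def params_array(self) -> np.ndarray:
        return np.array([getattr(self.params, n) for n in self.param_names])

    @property
    def hazard_spec(self) -> HazardSpec:
        return HazardSpec(self.model.model, self.params)

    def predict(self, ages=None) -> np.ndarray:
        """Model hazard at the given ages (default: the fitted ages)."""
        ages = self.model.ages if ages is None else np.asarray(ages, dtype=float)
        return self.hazard_spec.hazard(ages)

    def to_row(self) -> dict:
        row = {
            "model": self.model_tag,
            "n_points": self.n_points,
            "r2": self.r2,
            "rmse": self.rmse,
            "aic": self.aic,
            "converged": self.converged,
        }
        if self.params is not None:
            row.update({n: getattr(self.params, n) for n in self.param_names})
        return row

    def summary(self) -> str:
        lines = [
            f"Hazard model fit: {self.model_tag}",
            "=" * 46,
            f"{'n ages used':<24}{self.n_points:>22d}",
            f"{'ages dropped (mx<=0)':<24}{self.model.n_dropped:>22d}",
            f"{'converged':<24}{str(self.converged):>22}",
            f"{'R^2 (log scale)':<24}{self.r2:>22.6f}",
            f"{'RMSE (log scale)':<24}{self.rmse:>22.6f}",
            f"{'AIC':<24}{self.aic:>22.4f}",
            "-" * 46,
        ]
        if self.params is not None:
            for name in self.param_names:
                lines.append(f"{name:<24}{getattr(self.params, name):>22.8g}")
        lines.append("=" * 46)
        return "\n".join(lines)


# spec-surface alias: a FitResult is the results object
FitResult = HazardFitResults


def fit_model(ages, mx, model_tag: str, init=None, bounds=None, seed: int = 0,
              max_age: float | None = None) -> HazardFitResults:
    """Functional wrapper: fit one hazard model to (ages, mx)."""
    return HazardModel(ages, mx, model=model_tag, max_age=max_age).fit(
        init=init, bounds=bounds, seed=seed
    )


@dataclass
class FitBatch:
    """Tidy per-(country, year, model) fit rows with parameter-trend access."""

    rows: pd.DataFrame

    def to_dataframe(self) -> pd.DataFrame:
        return self.rows

    def param_trend(self, param: str, model: str = "hda") -> pd.DataFrame:
        """Year-indexed series of one fitted parameter, one column per country."""
        sel = self.rows[(self.rows["model"] == model) & self.rows["error"].isna()]
        if param not in sel.columns:
            raise KeyError(f"parameter {param!r} not found for model {model!r}")
        return sel.pivot_table(index="year", columns="country", values=param)


def fit_batch(
    tables,
    models=("hda", "gmm", "siler", "heligman"),
    sex: str = "total",
    seed: int = 0,
    max_age: float | None = None,
) -> FitBatch:
    """Fit every model to every table; failures are flagged per row, not raised."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to fit")
    rows = []
    for tb in tables:
        for tag in models:
            base = {"country": tb.country, "year": tb.year, "model": tag, "error": None}
            try:
                res = HazardModel.from_table(tb, sex=sex, model=tag, max_age=max_age).fit(
                    seed=seed
                )
                row = res.to_row()
                row.pop("model")
                base.update(row)
            except Exception as exc:  # error isolation: batch continues
                base["error"] = f"{type(exc).__name__}: {exc}"
                base["converged"] = False
            rows.append(base)
    df = pd.DataFrame(rows)
    df["error"] = df["error"].astype("object")
    return FitBatch(rows=df)
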