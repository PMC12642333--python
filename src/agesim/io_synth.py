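"""Mortality-table I/O and synthetic data generation.

Reads and writes period life tables in the Human Mortality Database
"Mx 1x1" text layout (two preamble lines, then whitespace-delimited columns
``Year Age Female Male Total`` with ages 0..110+, missing cells "."), and
generates synthetic tables from an hDA hazard with multiplicative lognormal
noise so the whole fitting pipeline can be exercised without any download.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hazards import HDAParams, hda_hazard

__all__ = [
    "DEFAULT_SYNTH_PARAMS",
    "MortalityTable",
    "SynthSpec",
    "read_hmd_mx",
    "write_hmd_mx",
    "synth_mortality",
    "write_results",
]

_SEXES = ("female", "male", "total")

# Generating truth for synthetic recovery experiments. Human-like scales with
# every hDA feature visibly expressed (steep infant decline, juvenile plateau,
# a clear late-benefit dip around the lambda halfway age, Gompertz rise), so
# that all eight parameters are identifiable from the generated table.
DEFAULT_SYNTH_PARAMS = HDAParams(
    c=0.03,
    a=1.2e-4,
    b=0.085,
    gamma_max=0.027,
    h_gamma=2.0,
    lambda_max=0.005,
    n=0.25,
    k=35.0,
)


@dataclass
class MortalityTable:
    """One country-year of per-age central death rates mx.

    ``ages`` are integer years (strictly increasing, terminal open class
    flagged by ``open_age``); each sex column holds mx >= 0 with NaN for
    missing cells.
    """

    country: str
    year: int
    ages: np.ndarray
    female: np.ndarray
    male: np.ndarray
    total: np.ndarray
    open_age: bool = True

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=np.int64)
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        for sex in _SEXES:
            col = np.asarray(getattr(self, sex), dtype=float)
            if col.shape != self.ages.shape:
                raise ValueError(f"{sex} column length {col.size} != {self.ages.size} ages")
            if np.any(col[np.isfinite(col)] < 0):
                raise ValueError(f"{sex} mx contains negative values")
            setattr(self, sex, col)

    def mx(self, sex: str = "total") -> np.ndarray:
        if sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {sex!r}")
        return getattr(self, sex)

    def n_missing(self, sex: str = "total") -> int:
        return int(np.sum(~np.isfinite(self.mx(sex))))


def read_hmd_mx(path, sex: str = "total") -> list[MortalityTable]:
    """Parse an HMD "Mx 1x1" file into one table per year.

    ``sex`` only validates the selector used downstream; all three columns are
    retained. Tolerates space-aligned and tab-delimited dialects. The "110+"
    open class is stored as age 110 with the flag set; "." becomes NaN.
    """
    if sex not in _SEXES:
        raise ValueError(f"unknown sex selector {sex!r}; expected one of {_SEXES}")
    path = Path(path)
    lines = path.read_text().splitlines()
    country = lines[0].split(",")[0].strip() if lines else path.stem

    rows = []
    header_seen = False
    for ln_no, line in enumerate(lines, start=1):
        toks = line.split()
        if not toks:
            continue
        if toks[0].lower() == "year":
            header_seen = True
            continue
        if not toks[0].lstrip("-").isdigit():
            # preamble line (country/protocol banner)
            if header_seen or ln_no > 3:
                raise ValueError(f"{path}:{ln_no}: malformed data line: {line!r}")
            continue
        if len(toks) != 5:
            raise ValueError(
                f"{path}:{ln_no}: expected 5 columns (Year Age Female Male Total), got {len(toks)}"
            )
        year_s, age_s, f_s, m_s, t_s = toks
        open_cls = age_s.endswith("+")
        try:
            age = int(age_s.rstrip("+"))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln_no}: bad age {age_s!r}") from exc

        def val(s: str, _ln=ln_no) -> float:
            if s == ".":
                return np.nan
            try:
                return float(s)
            except ValueError as exc:
                raise ValueError(f"{path}:{_ln}: bad mx value {s!r}") from exc

        rows.append((int(year_s), age, open_cls, val(f_s), val(m_s), val(t_s)))

    if not rows:
        raise ValueError(f"{path}: no data rows found")
    df = pd.DataFrame(rows, columns=["year", "age", "open", "female", "male", "total"])
    tables = []
    for year, grp in df.groupby("year", sort=True):
        grp = grp.sort_values("age")
        tables.append(
            MortalityTable(
                country=country,
                year=int(year),
                ages=grp["age"].to_numpy(),
                female=grp["female"].to_numpy(),
                male=grp["male"].to_numpy(),
                total=grp["total"].to_numpy(),
                open_age=bool(grp["open"].iloc[-1]),
            )
        )
    return tables


def write_hmd_mx(tables: MortalityTable | list[MortalityTable], path) -> Path:
    """Serialize table(s) in the HMD Mx 1x1 layout (full float precision)."""
    if isinstance(tables, MortalityTable):
        tables = [tables]
    path = Path(path)

    def fmt(v: float) -> str:
        return "." if not np.isfinite(v) else format(v, ".17g")

    out = [f"{tables[0].country}, Mx 1x1", ""]
    out.append(f"{'Year':>6} {'Age':>5} {'Female':>24} {'Male':>24} {'Total':>24}")
    for tb in tables:
        for i, age in enumerate(tb.ages):
            age_s = f"{age}+" if (tb.open_age and i == tb.ages.size - 1) else str(age)
            out.append(
                f"{tb.year:>6} {age_s:>5} {fmt(tb.female[i]):>24} "
                f"{fmt(tb.male[i]):>24} {fmt(tb.total[i]):>24}"
            )
    path.write_text("\n".join(out) + "\n")
    return path


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic mortality table: hDA truth x lognormal noise.

    mx(x) = h_hDA(x) * exp(eps_x), eps_x ~ N(0, noise_sd^2) i.i.d.;
    noise_sd = 0 reproduces the model hazard exactly.
    """

    params: HDAParams
    ages: tuple[int, int] = (0, 110)
    noise_sd: float = 0.05
    seed: int = 0
    country: str = "Synthetic"
    year: int = 2000

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ages[1] < self.ages[0] or self.ages[0] < 0:
            raise ValueError(f"invalid age range {self.ages}")


def synth_mortality(spec: SynthSpec) -> MortalityTable:
    """Generate a seeded synthetic MortalityTable (same rates in all sex columns)."""
    ages = np.arange(spec.ages[0], spec.ages[1] + 1)
    h = np.asarray(hda_hazard(ages, spec.params), dtype=float)
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_sd, size=ages.size) if spec.noise_sd > 0 else 0.0
    mx = h * np.exp(eps)
    return MortalityTable(
        country=spec.country,
        year=spec.year,
        ages=ages,
        female=mx.copy(),
        male=mx.copy(),
        total=mx.copy(),
        open_age=True,
    )


def write_results(obj, path, format: str = "csv") -> Path:
    """Write a result object (Trajectory, FitnessGrid, DeltaB, FitBatch, or
    DataFrame) as tidy CSV or structured JSON at full float precision."""
    path = Path(path)
    if format not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")

    if hasattr(obj, "to_dataframe"):
        df = obj.to_dataframe()
    elif hasattr(obj, "to_dict") and format == "json":
        df = None
    elif isinstance(obj, pd.DataFrame):
        df = obj
    elif hasattr(obj, "to_dict"):
        df = pd.DataFrame([obj.to_dict()])
    else:
        raise TypeError(f"don't know how to serialize {type(obj).__name__}")

    if format == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        payload = obj.to_dict() if hasattr(obj, "to_dict") else df.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2, default=float))
    return path
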