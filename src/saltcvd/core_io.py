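"""Shared domain types, CSV schemas, and run configuration.

The pipeline works on dense annual single-age demographic tables for two
sexes. Everything on disk is plain UTF-8 CSV with a header row and '.'
decimal separator:

* ``population_1950.csv``   — sex, age, population (ages 0–70, start of 1950)
* ``births.csv``            — sex, year, births (1950–1997)
* ``mortality_1950.csv``    — sex, age, rate (ages 0–69)
* ``cvd_proportion.csv``    — year, proportion (1950–2017)
* ``salt_overall.csv``      — sex, year, grams_per_day (overall survey means)
* ``salt_by_group.csv``     — sex, year, age_group_start, age_group_end,
                              grams_per_day (10-year-group survey means)
* ``observed_mortality.csv``— sex, year, age, rate (calibration target surface)

Readers validate schema and the type invariants (non-negative stocks, rates
in [0, 1), dense age/year axes); a missing cell is an error, never imputed.

Year semantics: a row labelled year ``t`` describes the state at the start
of calendar year ``t`` and the flows during [t, t+1). Age in year ``t`` is
``t - birth_year`` (completed years at the start of ``t``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

SEXES = ("male", "female")


class SchemaError(ValueError):
    """A CSV file does not have the expected columns or dtypes."""


class ValidationError(ValueError):
    """A table violates a domain invariant (negative stock, gap in an axis...)."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Temporal scope of the simulation.

    The cohort range is tied to the observation window: the oldest cohort
    (``start_year - exit_age``) ages out in the first simulated year and the
    youngest (``end_year - adult_age``) just reaches adulthood in the last.
    With the defaults that is 118 birth cohorts, 1880–1997.
    """

    start_year: int = 1950
    end_year: int = 2017
    adult_age: int = 20
    exit_age: int = 70
    scenario_fractions: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.0)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.exit_age <= self.adult_age:
            raise ValidationError("exit_age must exceed adult_age")
        if self.end_year < self.start_year:
            raise ValidationError("end_year before start_year")
        for f in self.scenario_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"scenario fraction {f} outside [0, 1]")

    @property
    def min_cohort_year(self) -> int:
        return self.start_year - self.exit_age

    @property
    def max_cohort_year(self) -> int:
        return self.end_year - self.adult_age

    @property
    def n_cohorts(self) -> int:
        return self.max_cohort_year - self.min_cohort_year + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def cohorts(self) -> np.ndarray:
        return np.arange(self.min_cohort_year, self.max_cohort_year + 1)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "scenario_fractions" in raw:
            raw["scenario_fractions"] = tuple(float(x) for x in raw["scenario_fractions"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = {
            "start_year": self.start_year,
            "end_year": self.end_year,
            "adult_age": self.adult_age,
            "exit_age": self.exit_age,
            "scenario_fractions": list(self.scenario_fractions),
            "random_seed": self.random_seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# demography container
# ---------------------------------------------------------------------------


def _require_dense(index: pd.Index, lo: int, hi: int, name: str) -> None:
    expected = np.arange(lo, hi + 1)
    if len(index) != len(expected) or not np.array_equal(np.asarray(index), expected):
        raise ValidationError(f"{name}: axis must be dense {lo}..{hi}, got {len(index)} entries")


@dataclass
class DemographyInputs:
    """Population stocks and rates feeding the cohort engine.

    initial_population : DataFrame, index age 0..exit_age, columns SEXES
        Persons at the start of ``start_year`` (1950).
    births : DataFrame, index year start..max_cohort_year, columns SEXES
        Persons born each year; the inflow for post-1950 cohorts.
    observed_mortality : dict sex -> DataFrame, index age 0..exit_age-1,
        columns year start..end. All-cause rate per person-year, the
        calibration target.
    """

    initial_population: pd.DataFrame
    births: pd.DataFrame
    observed_mortality: dict[str, pd.DataFrame]
    config: RunConfig = field(default_factory=RunConfig)

    def validate(self) -> "DemographyInputs":
        cfg = self.config
        for df, name in ((self.initial_population, "initial_population"), (self.births, "births")):
            missing = set(SEXES) - set(df.columns)
            if missing:
                raise SchemaError(f"{name}: missing sex columns {sorted(missing)}")
            if not np.isfinite(df[list(SEXES)].to_numpy()).all():
                raise ValidationError(f"{name}: non-finite values")
            if (df[list(SEXES)].to_numpy() < 0).any():
                raise ValidationError(f"{name}: negative counts")
        _require_dense(self.initial_population.index, 0, cfg.exit_age, "initial_population ages")
        _require_dense(self.births.index, cfg.start_year, cfg.max_cohort_year, "births years")
        for sex in SEXES:
            surf = self.observed_mortality[sex]
            _require_dense(surf.index, 0, cfg.exit_age - 1, f"observed_mortality[{sex}] ages")
            _require_dense(surf.columns, cfg.start_year, cfg.end_year, f"observed_mortality[{sex}] years")
            vals = surf.to_numpy()
            if not np.isfinite(vals).all() or (vals < 0).any() or (vals >= 1).any():
                raise ValidationError(f"observed_mortality[{sex}]: rates must lie in [0, 1)")
        return self


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df[list(columns)].isna().any().any():
        raise ValidationError(f"{path}: missing cells are not allowed")
    return df[list(columns)]


def _check_sexes(df: pd.DataFrame, path: str | Path) -> None:
    bad = set(df["sex"].unique()) - set(SEXES)
    if bad:
        raise SchemaError(f"{path}: unknown sex labels {sorted(bad)}")


def read_population_1950(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ("sex", "age", "population"))
    _check_sexes(df, path)
    if (df["population"] < 0).any():
        raise ValidationError(f"{path}: negative population")
    piv = df.pivot(index="age", columns="sex", values="population").sort_index()
    return piv[[s for s in SEXES if s in piv.columns]]


def read_births(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ("sex", "year", "births"))
    _check_sexes(df, path)
    if (df["births"] < 0).any():
        raise ValidationError(f"{path}: negative birth count")
    piv = df.pivot(index="year", columns="sex", values="births").sort_index()
    return piv[[s for s in SEXES if s in piv.columns]]


def read_mortality_1950(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ("sex", "age", "rate"))
    _check_sexes(df, path)
    if ((df["rate"] < 0) | (df["rate"] >= 1)).any():
        raise ValidationError(f"{path}: rates must lie in [0, 1)")
    piv = df.pivot(index="age", columns="sex", values="rate").sort_index()
    return piv[[s for s in SEXES if s in piv.columns]]


def read_cvd_proportion(path: str | Path) -> pd.Series:
    df = _read_csv(path, ("year", "proportion"))
    if ((df["proportion"] < 0) | (df["proportion"] > 1)).any():
        raise ValidationError(f"{path}: proportions must lie in [0, 1]")
    s = df.set_index("year")["proportion"].sort_index()
    _require_dense(s.index, int(s.index.min()), int(s.index.max()), f"{path} years")
    return s


def read_salt_overall(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ("sex", "year", "grams_per_day"))
    _check_sexes(df, path)
    if (df["grams_per_day"] <= 0).any():
        raise ValidationError(f"{path}: salt intake must be positive")
    return df


def read_salt_by_group(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ("sex", "year", "age_group_start", "age_group_end", "grams_per_day"))
    _check_sexes(df, path)
    if (df["grams_per_day"] <= 0).any():
        raise ValidationError(f"{path}: salt intake must be positive")
    if (df["age_group_end"] < df["age_group_start"]).any():
        raise ValidationError(f"{path}: inverted age group")
    return df


def read_observed_mortality(path: str | Path) -> dict[str, pd.DataFrame]:
    df = _read_csv(path, ("sex", "year", "age", "rate"))
    _check_sexes(df, path)
    if ((df["rate"] < 0) | (df["rate"] >= 1)).any():
        raise ValidationError(f"{path}: rates must lie in [0, 1)")
    out: dict[str, pd.DataFrame] = {}
    for sex, sub in df.groupby("sex"):
        out[str(sex)] = sub.pivot(index="age", columns="year", values="rate").sort_index()
    return out


def read_inputs(bundle_dir: str | Path, config: RunConfig | None = None):
    """Read a full input bundle directory.

    Returns ``(DemographyInputs, cvd_proportion, salt_overall, salt_by_group)``,
    fully validated.
    """
    d = Path(bundle_dir)
    cfg = config or RunConfig()
    demo = DemographyInputs(
        initial_population=read_population_1950(d / "population_1950.csv"),
        births=read_births(d / "births.csv"),
        observed_mortality=read_observed_mortality(d / "observed_mortality.csv"),
        config=cfg,
    ).validate()
    cvd = read_cvd_proportion(d / "cvd_proportion.csv")
    _require_dense(cvd.index, cfg.start_year, cfg.end_year, "cvd_proportion years")
    salt_overall = read_salt_overall(d / "salt_overall.csv")
    salt_by_group = read_salt_by_group(d / "salt_by_group.csv")
    return demo, cvd, salt_overall, salt_by_group


def write_population_1950(df: pd.DataFrame, path: str | Path) -> None:
    long = df.stack().rename("population").reset_index()
    long.columns = ["age", "sex", "population"]
    long[["sex", "age", "population"]].to_csv(path, index=False)


def write_births(df: pd.DataFrame, path: str | Path) -> None:
    long = df.stack().rename("births").reset_index()
    long.columns = ["year", "sex", "births"]
    long[["sex", "year", "births"]].to_csv(path, index=False)


def write_mortality_1950(df: pd.DataFrame, path: str | Path) -> None:
    long = df.stack().rename("rate").reset_index()
    long.columns = ["age", "sex", "rate"]
    long[["sex", "age", "rate"]].to_csv(path, index=False)


def write_cvd_proportion(s: pd.Series, path: str | Path) -> None:
    s.rename("proportion").rename_axis("year").reset_index().to_csv(path, index=False)


def write_observed_mortality(surfaces: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    frames = []
    for sex in SEXES:
        long = surfaces[sex].stack().rename("rate").reset_index()
        long.columns = ["age", "year", "rate"]
        long["sex"] = sex
        frames.append(long[["sex", "year", "age", "rate"]])
    pd.concat(frames).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# simulation ledger
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "scenario",
    "sex",
    "year",
    "cohort",
    "population",
    "cvd_deaths",
    "other_deaths",
    "aged_out",
)


@dataclass
class SimulationResult:
    """Full stock/flow ledger of one scenario run.

    Arrays are indexed ``[year, cohort]`` on the axes in ``years`` /
    ``cohorts``. ``population`` is the start-of-year stock (after the birth
    inflow in a cohort's birth year); the flows are persons during the year.
    ``other_hazard`` / ``cvd_hazard`` keep the per-cell hazards used, which
    is convenient for scenario-invariance checks and cohort rate curves.
    """

    scenario: str
    years: np.ndarray
    cohorts: np.ndarray
    population: dict[str, np.ndarray]
    cvd_deaths: dict[str, np.ndarray]
    other_deaths: dict[str, np.ndarray]
    aged_out: dict[str, np.ndarray]
    cvd_hazard: dict[str, np.ndarray]
    other_hazard: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long ledger: one row per sex x year x instantiated cohort-year."""
        rows = []
        for sex in SEXES:
            ages = self.years[:, None] - self.cohorts[None, :]
            live = (ages >= 0) & (ages < 70) & (self.cohorts[None, :] <= self.years[:, None])
            yy, cc = np.nonzero(live)
            rows.append(
                pd.DataFrame(
                    {
                        "scenario": self.scenario,
                        "sex": sex,
                        "year": self.years[yy],
                        "cohort": self.cohorts[cc],
                        "population": self.population[sex][yy, cc],
                        "cvd_deaths": self.cvd_deaths[sex][yy, cc],
                        "other_deaths": self.other_deaths[sex][yy, cc],
                        "aged_out": self.aged_out[sex][yy, cc],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=list(RESULT_COLUMNS))
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["sex", "year", "cohort"], kind="stable").reset_index(drop=True)


def write_result(result: SimulationResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False)


def read_result(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, RESULT_COLUMNS)
    _check_sexes(df, path)
    if (df[["population", "cvd_deaths", "other_deaths", "aged_out"]].to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative stock or flow")
    return df
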