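"""Scenario runs and excess-mortality analytics.

The base run uses the actual salt surface; each counterfactual retains a
fraction f of the actual post-1950 salt change (f = 0.75, 0.5, 0.25, 0 —
f = 0 freezes intake at the 1950 level).  The period/cohort coefficients
fitted on the factual surface are held constant across scenarios.

Excess cardiovascular mortality is computed on death counts (persons), so
population feedback is included: extra deaths in a counterfactual shrink
its later population.  All excess figures cover adult ages 20–69, the
population the model is scoped to, even though the engine simulates ages
0–69.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .apc_mortality import APCParams, SaltEffectParams
from .cohort_engine import run_model
from .core_io import SEXES, DemographyInputs, RunConfig, SimulationResult, ValidationError
from .salt_exposure import SaltExposureSurface, counterfactual_salt


@dataclass(frozen=True)
class ScenarioSpec:
    effect_fraction: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValidationError(f"effect fraction {self.effect_fraction} outside [0, 1]")


def scenario_label(effect_fraction: float) -> str:
    if effect_fraction == 1.0:
        return "base"
    return f"{int(round(effect_fraction * 100))}pct_effect"


@dataclass
class ExcessTable:
    """Annual and accumulated excess CVD deaths of one scenario vs the base run."""

    scenario: str
    by_year: pd.DataFrame  # sex, year, base_cvd_deaths, scenario_cvd_deaths, absolute_excess, relative_excess_pct
    accumulated: dict[str, float]


def adult_cvd_deaths(
    result: SimulationResult, age_lo: int = 20, age_hi: int = 69
) -> pd.DataFrame:
    """Annual CVD deaths summed over cohorts aged ``age_lo``..``age_hi``."""
    ages = result.years[:, None] - result.cohorts[None, :]
    mask = (ages >= age_lo) & (ages <= age_hi)
    rows = []
    for sex in SEXES:
        totals = np.where(mask, result.cvd_deaths[sex], 0.0).sum(axis=1)
        rows.append(pd.DataFrame({"sex": sex, "year": result.years, "cvd_deaths": totals}))
    return pd.concat(rows, ignore_index=True)


def run_all_scenarios(
    inputs: DemographyInputs,
    params: APCParams,
    salt_actual: SaltExposureSurface,
    cfg: RunConfig | None = None,
    salt_effect: SaltEffectParams | None = None,
) -> dict[str, SimulationResult]:
    """One full simulation per configured effect fraction, shared inputs."""
    cfg = cfg or RunConfig()
    out: dict[str, SimulationResult] = {}
    for f in cfg.scenario_fractions:
        label = scenario_label(f)
        assumed = counterfactual_salt(salt_actual, f, anchor_year=cfg.start_year)
        out[label] = run_model(
            inputs, params, salt_actual, assumed, cfg, salt_effect, scenario=label
        )
    return out


def excess_table(
    base: SimulationResult,
    scenario: SimulationResult,
    age_lo: int = 20,
    age_hi: int = 69,
) -> ExcessTable:
    """Annual absolute/relative excess CVD deaths and accumulated totals."""
    if not (
        np.array_equal(base.years, scenario.years)
        and np.array_equal(base.cohorts, scenario.cohorts)
    ):
        raise ValidationError("base and scenario runs have mismatched axes")
    b = adult_cvd_deaths(base, age_lo, age_hi).rename(columns={"cvd_deaths": "base_cvd_deaths"})
    s = adult_cvd_deaths(scenario, age_lo, age_hi).rename(
        columns={"cvd_deaths": "scenario_cvd_deaths"}
    )
    df = b.merge(s, on=["sex", "year"])
    df["absolute_excess"] = df["scenario_cvd_deaths"] - df["base_cvd_deaths"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(
            df["base_cvd_deaths"] > 0,
            100.0 * df["absolute_excess"] / df["base_cvd_deaths"],
            0.0,
        )
    df["relative_excess_pct"] = rel
    accumulated = {
        sex: float(df.loc[df["sex"] == sex, "absolute_excess"].sum()) for sex in SEXES
    }
    return ExcessTable(scenario=scenario.scenario, by_year=df, accumulated=accumulated)


def cohort_curve(result: SimulationResult, birth_year: int, sex: str) -> pd.Series:
    """CVD mortality rate (per 1000 person-years) of one cohort over calendar time.

    Computed as annual CVD deaths over start-of-year population; covers the
    cohort's active years within the simulation window. A cohort with zero
    population yields an empty series.
    """
    if birth_year not in result.cohorts:
        raise ValidationError(f"cohort {birth_year} outside the simulated range")
    ci = int(np.flatnonzero(result.cohorts == birth_year)[0])
    pop = result.population[sex][:, ci]
    deaths = result.cvd_deaths[sex][:, ci]
    ages = result.years - birth_year
    live = (ages >= 0) & (ages < 70) & (pop > 0)
    return pd.Series(1000.0 * deaths[live] / pop[live], index=result.years[live], name=sex)


def excess_report(
    results: dict[str, SimulationResult],
    out_dir: str | Path | None = None,
    age_lo: int = 20,
    age_hi: int = 69,
    curve_cohorts: tuple[int, ...] = (1890, 1910, 1930, 1940, 1950, 1970),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Excess tables for every non-base scenario, plus selected cohort curves.

    Returns (excess_by_year, accumulated_excess, cohort_curves); writes the
    three CSVs if ``out_dir`` is given.
    """
    base = results["base"]
    by_year_frames, acc_rows, curve_rows = [], [], []
    for label, res in results.items():
        if label == "base":
            continue
        tab = excess_table(base, res, age_lo, age_hi)
        frame = tab.by_year.copy()
        frame.insert(2, "scenario", label)
        by_year_frames.append(frame)
        for sex in SEXES:
            acc_rows.append({"sex": sex, "scenario": label, "excess_deaths": tab.accumulated[sex]})
    for label, res in results.items():
        for sex in SEXES:
            for b in curve_cohorts:
                if b not in res.cohorts:
                    continue
                curve = cohort_curve(res, b, sex)
                curve_rows.append(
                    pd.DataFrame(
                        {
                            "scenario": label,
                            "sex": sex,
                            "cohort": b,
                            "year": curve.index,
                            "cvd_rate_per_1000": curve.to_numpy(),
                        }
                    )
                )
    excess_by_year = (
        pd.concat(by_year_frames, ignore_index=True) if by_year_frames else pd.DataFrame()
    )
    accumulated = pd.DataFrame(acc_rows)
    curves = pd.concat(curve_rows, ignore_index=True) if curve_rows else pd.DataFrame()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        excess_by_year.to_csv(out / "excess_by_year.csv", index=False)
        accumulated.to_csv(out / "accumulated_excess.csv", index=False)
        curves.to_csv(out / "cohort_curves.csv", index=False)
    return excess_by_year, accumulated, curves
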