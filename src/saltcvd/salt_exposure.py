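"""Reconstruction of the salt-intake exposure surface and its counterfactuals.

Japan's National (Health and) Nutrition Survey reports mean dietary salt
intake as overall annual averages for 1973–1994 and as sex x 10-year age
group averages for 1995–2017.  The exposure surface the simulation needs —
grams/day by calendar year x single age x sex back to 1900 — is rebuilt in
four steps:

1. fit an ordinary least-squares line to the overall series on a fit window
   (default 1973–1986, where the trend is close to linear) and back-cast it
   to the pre-survey years, capping male values at 20 g/day in 1942 and
   earlier (pre-war dietary records put male intake near that ceiling);
2. form, per sex and 10-year age group, the ratio of the group's mean over
   a reference window (default 1995–2017) to the overall mean over the same
   window;
3. multiply each year's overall mean (observed or back-cast) by the group
   ratio for all years <= 1994, and pass the reported group values through
   unchanged for 1995–2017; all single ages within a group share one value;
4. read off each birth cohort's intake at age 20 — the cohort-channel
   exposure ("salt at 20").

Counterfactual ("assumed") surfaces retain a fraction ``f`` of the actual
post-1950 change: ``f = 1`` reproduces the actual surface, ``f = 0`` freezes
intake at its 1950 level from 1950 onward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_io import SEXES, ValidationError

#: 10-year survey groups; the open group below 20 exists for completeness
#: only (the salt effect is switched off below age 20).
AGE_GROUPS: tuple[tuple[int, int], ...] = (
    (0, 19),
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
)


class ImputationError(ValueError):
    """Back-cast or surface assembly produced an invalid exposure value."""


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for rebuilding the exposure surface.

    ``backcast_start_year`` reaches 1900 so that the 1880 birth cohort has
    an age-20 value.  The male cap applies to back-cast years up to
    ``cap_end_year`` (1942) only.
    """

    fit_window: tuple[int, int] = (1973, 1986)
    backcast_start_year: int = 1900
    male_cap: float = 20.0
    cap_end_year: int = 1942
    ratio_reference_window: tuple[int, int] = (1995, 2017)

    def __post_init__(self) -> None:
        if self.male_cap <= 0:
            raise ValidationError("male_cap must be positive")
        if self.fit_window[1] < self.fit_window[0]:
            raise ValidationError("inverted fit window")


@dataclass
class SaltExposureSurface:
    """Salt intake by year x single age x sex, plus per-cohort intake at 20.

    ``salt[sex]`` is a DataFrame with index single age 0..69 and columns
    calendar year (backcast_start_year..2017).  ``salt_at_20[sex]`` is a
    Series indexed by birth year.
    """

    salt: dict[str, pd.DataFrame]
    salt_at_20: dict[str, pd.Series]

    def value(self, sex: str, year: int, age: int) -> float:
        return float(self.salt[sex].at[age, year])

    def copy(self) -> "SaltExposureSurface":
        return SaltExposureSurface(
            salt={s: df.copy() for s, df in self.salt.items()},
            salt_at_20={s: v.copy() for s, v in self.salt_at_20.items()},
        )


def write_salt_surface(surface: SaltExposureSurface, surface_path, at20_path) -> None:
    """Emit salt_surface.csv (sex,year,age,grams_per_day) and
    salt_at_20.csv (sex,birth_year,grams_per_day)."""
    rows = []
    for sex in SEXES:
        long = surface.salt[sex].stack().rename("grams_per_day").reset_index()
        long.columns = ["age", "year", "grams_per_day"]
        long["sex"] = sex
        rows.append(long[["sex", "year", "age", "grams_per_day"]])
    pd.concat(rows).to_csv(surface_path, index=False)
    at20 = []
    for sex in SEXES:
        s = surface.salt_at_20[sex].rename("grams_per_day").rename_axis("birth_year").reset_index()
        s["sex"] = sex
        at20.append(s[["sex", "birth_year", "grams_per_day"]])
    pd.concat(at20).to_csv(at20_path, index=False)


def fit_backcast_line(overall_series: pd.Series, window: tuple[int, int]) -> tuple[float, float]:
    """OLS line through the windowed points of a year-indexed series.

    Returns ``(slope, intercept)`` for ``value = intercept + slope * year``.
    """
    years = overall_series.index.to_numpy(dtype=float)
    mask = (years >= window[0]) & (years <= window[1])
    if mask.sum() < 2:
        raise ImputationError(f"need >= 2 points inside fit window {window}, got {int(mask.sum())}")
    slope, intercept = np.polyfit(years[mask], overall_series.to_numpy(dtype=float)[mask], 1)
    return float(slope), float(intercept)


def backcast_overall(
    line: tuple[float, float],
    years: np.ndarray | range,
    sex: str,
    cfg: ImputationConfig,
) -> pd.Series:
    """Evaluate the fitted line on pre-survey years, applying the male cap.

    Only males are capped (at ``male_cap`` g/day for years <= 1942); female
    back-casts are used as fitted.
    """
    slope, intercept = line
    yrs = np.asarray(list(years), dtype=int)
    vals = intercept + slope * yrs.astype(float)
    if sex == "male":
        vals = np.where(yrs <= cfg.cap_end_year, np.minimum(vals, cfg.male_cap), vals)
    if (vals <= 0).any():
        bad = yrs[vals <= 0]
        raise ImputationError(f"non-positive back-cast salt for {sex} in years {bad.tolist()}")
    return pd.Series(vals, index=yrs)


def group_ratios(
    group_means: pd.DataFrame,
    overall_means: dict[str, pd.Series],
    window: tuple[int, int] = (1995, 2017),
) -> dict[str, dict[tuple[int, int], float]]:
    """Ratio of each group's window-mean to the overall window-mean, per sex.

    ``group_means`` is the long salt_by_group table (sex, year,
    age_group_start, age_group_end, grams_per_day).
    """
    ratios: dict[str, dict[tuple[int, int], float]] = {}
    for sex in SEXES:
        overall = overall_means[sex]
        sel = overall[(overall.index >= window[0]) & (overall.index <= window[1])]
        denom = float(sel.mean())
        if denom == 0.0:
            raise ImputationError(f"zero overall mean for {sex} in {window}")
        sub = group_means[
            (group_means["sex"] == sex)
            & (group_means["year"] >= window[0])
            & (group_means["year"] <= window[1])
        ]
        ratios[sex] = {}
        for (lo, hi), grp in sub.groupby(["age_group_start", "age_group_end"]):
            ratios[sex][(int(lo), int(hi))] = float(grp["grams_per_day"].mean()) / denom
    return ratios


def _group_of(age: int, groups: tuple[tuple[int, int], ...]) -> tuple[int, int]:
    for lo, hi in groups:
        if lo <= age <= hi:
            return (lo, hi)
    # single ages below the youngest surveyed group take its value
    lo, hi = min(groups)
    if age < lo:
        return (lo, hi)
    raise ImputationError(f"no age group covers age {age}")


def build_salt_matrix(
    overall: dict[str, pd.Series],
    ratios: dict[str, dict[tuple[int, int], float]],
    group_values: pd.DataFrame,
    last_scaled_year: int = 1994,
    ages: np.ndarray | range = range(0, 70),
    cfg: ImputationConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the year x single-age surface per sex.

    Years up to ``last_scaled_year``: overall mean x group ratio, constant
    over single ages within each 10-year group.  Later years: the reported
    group values passed through unchanged.  The male pre-war ceiling is
    enforced cell-wise: no male cell in ``cap_end_year`` or earlier exceeds
    ``male_cap`` g/day.
    """
    cfg = cfg or ImputationConfig()
    ages = np.asarray(list(ages), dtype=int)
    surfaces: dict[str, pd.DataFrame] = {}
    for sex in SEXES:
        sub = group_values[group_values["sex"] == sex]
        groups = tuple(sorted({(int(l), int(h)) for l, h in zip(sub["age_group_start"], sub["age_group_end"])}))
        late_years = np.sort(sub["year"].unique())
        early_years = overall[sex].index[overall[sex].index <= last_scaled_year]
        years = np.concatenate([early_years.to_numpy(dtype=int), late_years.astype(int)])
        mat = np.empty((len(ages), len(years)))
        late_lookup = {
            (int(r.year), (int(r.age_group_start), int(r.age_group_end))): float(r.grams_per_day)
            for r in sub.itertuples()
        }
        for j, year in enumerate(years):
            for i, age in enumerate(ages):
                grp = _group_of(int(age), groups)
                if year <= last_scaled_year:
                    if grp not in ratios[sex]:
                        raise ImputationError(f"no ratio for {sex} group {grp}")
                    mat[i, j] = float(overall[sex].loc[year]) * ratios[sex][grp]
                else:
                    try:
                        mat[i, j] = late_lookup[(int(year), grp)]
                    except KeyError as exc:
                        raise ImputationError(f"missing group value for {sex} {year} {grp}") from exc
        if sex == "male":
            capped = years <= cfg.cap_end_year
            mat[:, capped] = np.minimum(mat[:, capped], cfg.male_cap)
        surfaces[sex] = pd.DataFrame(mat, index=ages, columns=years)
    return surfaces


def salt_at_age20(
    surface: dict[str, pd.DataFrame],
    cohorts: np.ndarray | range = range(1880, 1998),
) -> dict[str, pd.Series]:
    """Each cohort's intake in the year it turns 20 (at age 20)."""
    cohorts = np.asarray(list(cohorts), dtype=int)
    out: dict[str, pd.Series] = {}
    for sex in SEXES:
        df = surface[sex]
        vals = np.empty(len(cohorts))
        for k, b in enumerate(cohorts):
            year = int(b) + 20
            if year not in df.columns:
                raise ImputationError(f"surface does not cover year {year} for cohort {b}")
            vals[k] = df.at[20, year]
        out[sex] = pd.Series(vals, index=cohorts)
    return out


def impute_salt(
    salt_overall: pd.DataFrame,
    salt_by_group: pd.DataFrame,
    cfg: ImputationConfig | None = None,
    cohorts: np.ndarray | range = range(1880, 1998),
) -> SaltExposureSurface:
    """Full survey-to-surface pipeline.

    The overall reference series for the ratio window (1995–2017, where the
    survey reports only group means) is taken as the unweighted mean of the
    group means in each year.
    """
    cfg = cfg or ImputationConfig()
    surfaces_overall: dict[str, pd.Series] = {}
    reference_overall: dict[str, pd.Series] = {}
    for sex in SEXES:
        sub = salt_overall[salt_overall["sex"] == sex]
        survey = sub.set_index("year")["grams_per_day"].sort_index()
        if survey.empty:
            raise ImputationError(f"no overall survey series for {sex}")
        line = fit_backcast_line(survey, cfg.fit_window)
        pre_years = range(cfg.backcast_start_year, int(survey.index.min()))
        backcast = backcast_overall(line, pre_years, sex, cfg)
        surfaces_overall[sex] = pd.concat([backcast, survey]).sort_index()
        grp = salt_by_group[salt_by_group["sex"] == sex]
        reference_overall[sex] = grp.groupby("year")["grams_per_day"].mean()
    ratios = group_ratios(salt_by_group, reference_overall, cfg.ratio_reference_window)
    surface = build_salt_matrix(surfaces_overall, ratios, salt_by_group, cfg=cfg)
    return SaltExposureSurface(salt=surface, salt_at_20=salt_at_age20(surface, cohorts))


def counterfactual_salt(
    surface: SaltExposureSurface,
    effect_fraction: float,
    anchor_year: int = 1950,
) -> SaltExposureSurface:
    """Counterfactual surface retaining a fraction of the post-anchor change.

    For years ``t >= anchor_year`` each cell is moved toward its anchor-year
    value: ``assumed = actual + (1 - f) * (actual(anchor) - actual(t))``.
    ``f = 1`` is the identity (base run); ``f = 0`` freezes the anchor level.
    Years before the anchor are untouched, so cohorts reaching age 20 before
    the anchor keep their actual intake at 20.
    """
    f = effect_fraction
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"effect fraction {f} outside [0, 1]")
    if f == 1.0:
        return surface.copy()
    assumed: dict[str, pd.DataFrame] = {}
    for sex in SEXES:
        df = surface.salt[sex].copy()
        if anchor_year not in df.columns:
            raise ImputationError(f"anchor year {anchor_year} not covered by the surface")
        anchor = df[anchor_year].to_numpy()
        later = df.columns[df.columns >= anchor_year]
        vals = df[later].to_numpy()
        df[later] = vals + (1.0 - f) * (anchor[:, None] - vals)
        assumed[sex] = df
    cohorts = next(iter(surface.salt_at_20.values())).index
    return SaltExposureSurface(salt=assumed, salt_at_20=salt_at_age20(assumed, cohorts))
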