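"""Synthetic input bundles with the statistical structure of the real sources.

Every table the pipeline consumes — the 1950 census pyramid, annual births,
the 1950 mortality schedule, the CVD share of deaths, the two salt survey
tables, and the observed mortality surface — can be generated here with
known ground truth, so imputation, calibration, simulation, and the excess
analytics are all testable without any download.

What the generator emulates:

* a postwar pyramid tapering exponentially with age (~1e6 persons per
  single age and sex at age 0);
* births around 1.5 million/year in 1950, declining 1% per year;
* a Gompertz 1950 mortality schedule ``a * exp(b * age)`` with an infant
  offset, women scaled below men;
* a CVD share of deaths rising from 0.20 to 0.40 by 1970 then easing back
  to 0.30 by 2017;
* smoothly declining salt intake (men 20 -> 11 g/day, women 14 -> 9 g/day
  over 1950–2017) with a mid-age peak (~1.1x overall) and a young-adult
  trough (~0.9x), published the way the survey publishes it: overall means
  only for 1973–1994, sex x 10-year-group means for 1995–2017;
* an observed mortality surface produced by the APC model itself at known
  (p, c) — by default the coefficients the calibration is expected to
  recover — with optional multiplicative log-normal noise.

The overall salt path is piecewise linear (exactly linear through the
back-cast fit window), so the survey imputation can reconstruct the true
surface exactly; its pre-1950 extension is clamped at 25 g/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationSpec, model_rate_surface
from .core_io import (
    SEXES,
    DemographyInputs,
    RunConfig,
    ValidationError,
    write_births,
    write_cvd_proportion,
    write_mortality_1950,
    write_observed_mortality,
    write_population_1950,
)
from .apc_mortality import APCParams
from .salt_exposure import AGE_GROUPS, SaltExposureSurface, salt_at_age20


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    seed: int = 0
    # demography
    pyramid_base: dict[str, float] = field(
        default_factory=lambda: {"male": 1.05e6, "female": 1.0e6}
    )
    pyramid_taper: float = 0.028  # exponential decline per year of age
    birth_level: float = 1.5e6  # total births/year in 1950
    birth_decline: float = 0.01  # relative decline per year
    male_birth_fraction: float = 0.512
    # 1950 mortality schedule: a * exp(b * age), plus an infant offset at age 0
    gompertz_a: float = 5e-5
    gompertz_b: float = 0.085
    infant_rate: float = 0.02
    female_mortality_scale: float = 0.85
    # CVD share of all deaths
    cvd_start: float = 0.20
    cvd_peak: float = 0.40
    cvd_peak_year: int = 1970
    cvd_end: float = 0.30
    # salt paths (g/day): value in 1950, at the survey-format switch, in 2017
    salt_1950: dict[str, float] = field(
        default_factory=lambda: {"male": 20.0, "female": 14.0}
    )
    salt_1994: dict[str, float] = field(
        default_factory=lambda: {"male": 12.0, "female": 9.6}
    )
    salt_2017: dict[str, float] = field(
        default_factory=lambda: {"male": 11.0, "female": 9.0}
    )
    salt_max: float = 25.0
    # raw age-gradient over the 10-year groups (normalised to mean 1)
    age_profile: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "male": (0.78, 0.90, 1.02, 1.08, 1.12, 1.05),
            "female": (0.80, 0.92, 1.02, 1.08, 1.10, 1.03),
        }
    )
    # ground-truth period/cohort coefficients and observation noise
    true_p: dict[str, float] = field(
        default_factory=lambda: {"male": 0.97777, "female": 0.962632}
    )
    true_c: dict[str, float] = field(
        default_factory=lambda: {"male": 0.999826, "female": 0.998483}
    )
    sigma: float = 0.0  # sd of N(0, sigma^2) noise on log observed rates

    def validate(self) -> "SynthConfig":
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")
        for sex in SEXES:
            for v in (
                self.pyramid_base[sex],
                self.salt_1950[sex],
                self.salt_1994[sex],
                self.salt_2017[sex],
                self.true_p[sex],
                self.true_c[sex],
            ):
                if v <= 0:
                    raise ValidationError("config values must be positive")
            if not self.salt_1950[sex] < self.salt_max:
                raise ValidationError("salt paths must stay below salt_max")
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValidationError("Gompertz parameters must be positive")
        return self


@dataclass
class SyntheticBundle:
    """Everything one run of the pipeline needs, plus the ground truth."""

    demography: DemographyInputs
    cvd_proportion: pd.Series
    salt_overall: pd.DataFrame
    salt_by_group: pd.DataFrame
    m1950: dict[str, np.ndarray]
    true_salt: SaltExposureSurface
    config: SynthConfig


def _normalised_profile(cfg: SynthConfig, sex: str) -> dict[tuple[int, int], float]:
    raw = np.asarray(cfg.age_profile[sex], dtype=float)
    if len(raw) != len(AGE_GROUPS):
        raise ValidationError("age profile must have one entry per age group")
    norm = raw / raw.mean()
    return dict(zip(AGE_GROUPS, norm))


def _overall_salt(cfg: SynthConfig, sex: str, years: np.ndarray) -> np.ndarray:
    """Piecewise-linear overall mean: linear 1950–1994 (extended backwards,
    clamped at salt_max), then linear 1994–2017."""
    v50, v94, v17 = cfg.salt_1950[sex], cfg.salt_1994[sex], cfg.salt_2017[sex]
    early_slope = (v94 - v50) / (1994 - 1950)
    late_slope = (v17 - v94) / (2017 - 1994)
    years = np.asarray(years, dtype=float)
    vals = np.where(
        years <= 1994,
        v50 + early_slope * (years - 1950),
        v94 + late_slope * (years - 1994),
    )
    return np.minimum(vals, cfg.salt_max)


def generate_demography(
    cfg: SynthConfig, run: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Deterministic census pyramid, births, 1950 schedule and CVD share.

    Returns ``(initial_population, births, m1950, cvd_proportion)`` on the
    axes `core_io` expects.
    """
    cfg.validate()
    run = run or RunConfig()
    ages_full = np.arange(0, run.exit_age + 1)
    pop = pd.DataFrame(
        {
            sex: cfg.pyramid_base[sex] * np.exp(-cfg.pyramid_taper * ages_full)
            for sex in SEXES
        },
        index=pd.Index(ages_full, name="age"),
    )
    birth_years = np.arange(run.start_year, run.max_cohort_year + 1)
    level = cfg.birth_level * (1.0 - cfg.birth_decline) ** (birth_years - run.start_year)
    births = pd.DataFrame(
        {
            "male": cfg.male_birth_fraction * level,
            "female": (1.0 - cfg.male_birth_fraction) * level,
        },
        index=pd.Index(birth_years, name="year"),
    )
    ages = np.arange(0, run.exit_age)
    base = cfg.gompertz_a * np.exp(cfg.gompertz_b * ages)
    base[0] += cfg.infant_rate
    m1950 = pd.DataFrame(
        {"male": base, "female": cfg.female_mortality_scale * base},
        index=pd.Index(ages, name="age"),
    )
    years = np.arange(run.start_year, run.end_year + 1)
    rise = cfg.cvd_start + (cfg.cvd_peak - cfg.cvd_start) * np.clip(
        (years - run.start_year) / (cfg.cvd_peak_year - run.start_year), 0, 1
    )
    fall = cfg.cvd_peak + (cfg.cvd_end - cfg.cvd_peak) * np.clip(
        (years - cfg.cvd_peak_year) / (run.end_year - cfg.cvd_peak_year), 0, 1
    )
    cvd = pd.Series(np.where(years <= cfg.cvd_peak_year, rise, fall), index=pd.Index(years, name="year"))
    return pop, births, m1950, cvd


def true_salt_surface(
    cfg: SynthConfig,
    years: np.ndarray | range = range(1900, 2018),
    ages: np.ndarray | range = range(0, 70),
) -> SaltExposureSurface:
    """The smooth ground-truth exposure surface the surveys sample from."""
    cfg.validate()
    years = np.asarray(list(years), dtype=int)
    ages = np.asarray(list(ages), dtype=int)
    surf: dict[str, pd.DataFrame] = {}
    for sex in SEXES:
        overall = _overall_salt(cfg, sex, years)
        profile = _normalised_profile(cfg, sex)
        ratio_by_age = np.empty(len(ages))
        for i, a in enumerate(ages):
            for (lo, hi), r in profile.items():
                if lo <= a <= hi:
                    ratio_by_age[i] = r
                    break
        mat = np.minimum(ratio_by_age[:, None] * overall[None, :], cfg.salt_max)
        surf[sex] = pd.DataFrame(mat, index=ages, columns=years)
    return SaltExposureSurface(salt=surf, salt_at_20=salt_at_age20(surf))


def generate_salt_surveys(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survey tables as the NHNS publishes them, sampled from the truth.

    ``salt_overall.csv``-shaped rows for 1973–1994 (overall means only) and
    ``salt_by_group.csv``-shaped rows for 1995–2017 (sex x 10-year groups).
    """
    cfg.validate()
    overall_rows = []
    group_rows = []
    for sex in SEXES:
        yrs = np.arange(1973, 1995)
        for y, v in zip(yrs, _overall_salt(cfg, sex, yrs)):
            overall_rows.append({"sex": sex, "year": int(y), "grams_per_day": float(v)})
        profile = _normalised_profile(cfg, sex)
        late = np.arange(1995, 2018)
        late_overall = _overall_salt(cfg, sex, late)
        for y, v in zip(late, late_overall):
            for (lo, hi), r in profile.items():
                group_rows.append(
                    {
                        "sex": sex,
                        "year": int(y),
                        "age_group_start": lo,
                        "age_group_end": hi,
                        "grams_per_day": float(min(r * v, cfg.salt_max)),
                    }
                )
    return pd.DataFrame(overall_rows), pd.DataFrame(group_rows)


def generate_observed_mortality(
    m1950: pd.DataFrame | dict[str, np.ndarray],
    cfg: SynthConfig,
    sigma: float | None = None,
    seed: int | None = None,
    run: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Mortality surface from the APC model at the ground-truth (p, c).

    With ``sigma > 0`` each cell is multiplied by exp(N(0, sigma^2)) drawn
    from a generator seeded with ``seed`` (falling back to the config seed),
    clipped below 1 so rates stay valid.
    """
    cfg.validate()
    run = run or RunConfig()
    sigma = cfg.sigma if sigma is None else sigma
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    sched = {
        sex: (
            np.asarray(m1950[sex], dtype=float)
            if not isinstance(m1950, pd.DataFrame)
            else m1950[sex].to_numpy(dtype=float)
        )
        for sex in SEXES
    }
    spec = CalibrationSpec(
        age_range=(0, run.exit_age - 1), year_range=(run.start_year, run.end_year)
    )
    dummy_years = pd.Series(1.0, index=np.arange(run.start_year, run.end_year + 1))
    params = APCParams(
        m1950=sched, p=dict(cfg.true_p), c=dict(cfg.true_c), cvd_proportion=dummy_years
    ).validate()
    surfaces = model_rate_surface(params, spec)
    if sigma > 0:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        for sex in SEXES:
            noise = np.exp(rng.normal(0.0, sigma, surfaces[sex].shape))
            surfaces[sex] = (surfaces[sex] * noise).clip(upper=0.999999)
    return surfaces


def generate_bundle(
    cfg: SynthConfig | None = None,
    out_dir: str | Path | None = None,
    run: RunConfig | None = None,
) -> SyntheticBundle:
    """Full input bundle; optionally written as the canonical CSV files."""
    cfg = (cfg or SynthConfig()).validate()
    run = run or RunConfig()
    pop, births, m1950, cvd = generate_demography(cfg, run)
    observed = generate_observed_mortality(m1950, cfg, run=run)
    salt_overall, salt_by_group = generate_salt_surveys(cfg)
    demo = DemographyInputs(
        initial_population=pop, births=births, observed_mortality=observed, config=run
    ).validate()
    bundle = SyntheticBundle(
        demography=demo,
        cvd_proportion=cvd,
        salt_overall=salt_overall,
        salt_by_group=salt_by_group,
        m1950={sex: m1950[sex].to_numpy(dtype=float) for sex in SEXES},
        true_salt=true_salt_surface(cfg),
        config=cfg,
    )
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        write_population_1950(pop, d / "population_1950.csv")
        write_births(births, d / "births.csv")
        write_mortality_1950(m1950, d / "mortality_1950.csv")
        write_cvd_proportion(cvd, d / "cvd_proportion.csv")
        write_observed_mortality(observed, d / "observed_mortality.csv")
        salt_overall.to_csv(d / "salt_overall.csv", index=False)
        salt_by_group.to_csv(d / "salt_by_group.csv", index=False)
    return bundle
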