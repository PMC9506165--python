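"""Multiplicative age-period-cohort hazard model with a salt-effect channel.

Total mortality at single age ``a`` in calendar year ``t`` for the cohort
born in ``b = t - a`` is modeled as the product

    m(a, t) = m1950(a) * p^(t - 1950) * c^(b - 1880)

where ``m1950`` is the 1950 age schedule (age effect), ``p`` the annual
period coefficient and ``c`` the per-birth-year cohort coefficient, fitted
separately by sex.  The total hazard splits into a CVD hazard
(year-specific share of deaths, salt-sensitive) and an other-cause hazard
(salt-insensitive):

    cvd(a, t)   = m(a, t) * prop(t) * M(delta_p, delta_c, a)
    other(a, t) = m(a, t) * (1 - prop(t))

The salt multiplier ``M`` implements the epidemiological anchor that
+10 mmol/day (0.584 g) of salt raises CVD mortality by 1%, split 1:1
between the period channel (assumed - actual intake this year) and the
cohort channel (assumed - actual intake at age 20):

    M = 1.01^((0.5 * delta_p + 0.5 * delta_c) / 0.584)     for a >= 20
    M = 1                                                  for a < 20

The power-law form composes over the two channels and stays positive for
any finite deltas; a linear form (1 + 0.01 * delta/0.584) is available as a
config switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SEXES, ValidationError


@dataclass
class APCParams:
    """Fitted hazard-model parameters for both sexes.

    m1950 : dict sex -> ndarray of rates per person-year, indexed by single
        age 0..69 (the age effect).
    p, c : dict sex -> dimensionless coefficients (period, cohort).
    cvd_proportion : Series, year -> share of deaths that are cardiovascular.
    """

    m1950: dict[str, np.ndarray]
    p: dict[str, float]
    c: dict[str, float]
    cvd_proportion: pd.Series
    cohort_reference_year: int = 1880
    base_year: int = 1950

    def validate(self) -> "APCParams":
        for sex in SEXES:
            sched = np.asarray(self.m1950[sex])
            if (sched < 0).any() or (sched >= 1).any():
                raise ValidationError(f"m1950[{sex}] must lie in [0, 1)")
            if self.p[sex] <= 0 or self.c[sex] <= 0:
                raise ValidationError(f"period/cohort coefficients must be positive ({sex})")
        if ((self.cvd_proportion < 0) | (self.cvd_proportion > 1)).any():
            raise ValidationError("cvd_proportion must lie in [0, 1]")
        return self


@dataclass(frozen=True)
class SaltEffectParams:
    """Salt-to-CVD-mortality dose-response constants.

    One unit is 10 mmol/day of sodium as salt (0.584 g/day), associated with
    a 1% change in CVD mortality, split equally between the period and
    cohort channels and applied only from age 20 on.
    """

    percent_per_unit: float = 1.0
    grams_per_unit: float = 0.584
    period_weight: float = 0.5
    cohort_weight: float = 0.5
    min_effect_age: int = 20
    form: str = "power"  # or "linear"

    def __post_init__(self) -> None:
        if self.grams_per_unit <= 0:
            raise ValidationError("grams_per_unit must be positive")
        if abs(self.period_weight + self.cohort_weight - 1.0) > 1e-12:
            raise ValidationError("period and cohort weights must sum to 1")
        if self.form not in ("power", "linear"):
            raise ValidationError(f"unknown effect form {self.form!r}")


def baseline_hazard(age, year, birth_year, sex: str, params: APCParams):
    """Total mortality hazard m1950(age) * p^(year-1950) * c^(birth-ref).

    Accepts scalars or broadcastable integer arrays; ``birth_year`` must
    equal ``year - age`` elementwise.
    """
    age = np.asarray(age)
    year = np.asarray(year)
    birth_year = np.asarray(birth_year)
    if np.any(birth_year != year - age):
        raise ValidationError("birth_year must equal year - age")
    sched = np.asarray(params.m1950[sex])
    if np.any(age < 0) or np.any(age >= len(sched)):
        raise ValidationError(f"age outside the 0..{len(sched) - 1} mortality table")
    h = (
        sched[age]
        * params.p[sex] ** (year - params.base_year)
        * params.c[sex] ** (birth_year - params.cohort_reference_year)
    )
    return h if h.shape else float(h)


def salt_effect_multiplier(delta_period, delta_cohort, age, se: SaltEffectParams | None = None):
    """Dimensionless CVD-hazard multiplier for given salt differences (g/day).

    Deltas are assumed-minus-actual intake: positive deltas (more salt in
    the counterfactual) raise the hazard. Returns exactly 1 below the
    minimum effect age. Vectorized over broadcastable inputs.
    """
    se = se or SaltEffectParams()
    dp = np.asarray(delta_period, dtype=float)
    dc = np.asarray(delta_cohort, dtype=float)
    age = np.asarray(age)
    if not (np.isfinite(dp).all() and np.isfinite(dc).all()):
        raise ValidationError("salt deltas must be finite")
    units = (se.period_weight * dp + se.cohort_weight * dc) / se.grams_per_unit
    if se.form == "power":
        mult = (1.0 + se.percent_per_unit / 100.0) ** units
    else:
        # the linear form can hit zero for large negative deltas; floor it
        mult = np.maximum(1.0 + se.percent_per_unit / 100.0 * units, 0.0)
    mult = np.where(age < se.min_effect_age, 1.0, mult)
    return mult if mult.shape else float(mult)


def cause_specific_hazards(total_hazard, year, multiplier, params: APCParams):
    """Split the total hazard into (cvd_hazard, other_hazard).

    The other-cause hazard never sees the salt multiplier, so it is
    identical across scenarios.
    """
    year = np.asarray(year)
    try:
        prop = params.cvd_proportion.loc[np.atleast_1d(year)].to_numpy()
    except KeyError as exc:
        raise ValidationError(f"year outside the CVD-proportion table: {exc}") from exc
    prop = prop.reshape(np.shape(year)) if np.shape(year) else float(prop[0])
    total = np.asarray(total_hazard, dtype=float)
    cvd = total * prop * np.asarray(multiplier, dtype=float)
    other = total * (1.0 - prop)
    if cvd.shape or np.shape(other):
        return cvd, other
    return float(cvd), float(other)


def neutral_params(m1950: dict[str, np.ndarray], cvd_proportion: pd.Series) -> APCParams:
    """APCParams with p = c = 1 (the period/cohort-neutral limit)."""
    return APCParams(
        m1950={s: np.asarray(m1950[s], dtype=float) for s in SEXES},
        p=dict.fromkeys(SEXES, 1.0),
        c=dict.fromkeys(SEXES, 1.0),
        cvd_proportion=cvd_proportion,
    ).validate()


def with_coefficients(params: APCParams, p: dict[str, float], c: dict[str, float]) -> APCParams:
    out = APCParams(
        m1950=params.m1950,
        p=dict(p),
        c=dict(c),
        cvd_proportion=params.cvd_proportion,
        cohort_reference_year=params.cohort_reference_year,
        base_year=params.base_year,
    )
    return out.validate()
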