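"""Calibration of the period and cohort coefficients to a mortality surface.

The base (factual) run requires the two free coefficients of the
multiplicative age-period-cohort hazard — p (period) and c (cohort) — to
reproduce the observed all-cause mortality surface by single age and year.
They are fitted independently per sex by minimising the sum of squared
differences of log rates over the full age x year grid with a
derivative-free Nelder-Mead simplex (restarted once at its own optimum),
starting from the neutral point p = c = 1 inside the box [0.8, 1.2]^2.

Log-scale residuals are the default because mortality spans two orders of
magnitude across age; a linear-scale objective is available.  Because the
1950 age schedule is held fixed (not refit), the two coefficients are
identifiable from a noiseless surface: the period exponent grows along
years while the cohort exponent also varies along the age diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .apc_mortality import APCParams
from .core_io import SEXES, ValidationError


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationSpec:
    age_range: tuple[int, int] = (0, 69)
    year_range: tuple[int, int] = (1950, 2017)
    initial: tuple[float, float] = (1.0, 1.0)
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.8, 1.2), (0.8, 1.2))
    loss_tol: float = 1e-10
    max_iter: int = 2000
    scale: str = "log"  # or "linear"
    base_year: int = 1950
    cohort_reference_year: int = 1880

    def __post_init__(self) -> None:
        for x, (lo, hi) in zip(self.initial, self.bounds):
            if not lo <= x <= hi:
                raise ValidationError("initial point outside bounds")
        if self.scale not in ("log", "linear"):
            raise ValidationError(f"unknown loss scale {self.scale!r}")


@dataclass
class CalibrationResult:
    p: dict[str, float]
    c: dict[str, float]
    loss: dict[str, float]
    iterations: dict[str, int]
    converged: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": list(SEXES),
                "p": [self.p[s] for s in SEXES],
                "c": [self.c[s] for s in SEXES],
                "loss": [self.loss[s] for s in SEXES],
                "converged": [self.converged[s] for s in SEXES],
            }
        )


def model_rate_surface(
    params: APCParams, spec: CalibrationSpec | None = None
) -> dict[str, pd.DataFrame]:
    """Baseline total-mortality surface on the calibration grid (base run)."""
    spec = spec or CalibrationSpec()
    ages = np.arange(spec.age_range[0], spec.age_range[1] + 1)
    years = np.arange(spec.year_range[0], spec.year_range[1] + 1)
    out: dict[str, pd.DataFrame] = {}
    for sex in SEXES:
        sched = np.asarray(params.m1950[sex], dtype=float)
        if ages.max() >= len(sched):
            raise ValidationError("age range exceeds the 1950 mortality table")
        period = params.p[sex] ** (years - params.base_year)
        births = years[None, :] - ages[:, None]
        cohort = params.c[sex] ** (births - params.cohort_reference_year)
        out[sex] = pd.DataFrame(sched[ages][:, None] * period[None, :] * cohort, index=ages, columns=years)
    return out


def _surface_array(p: float, c: float, sched: np.ndarray, spec: CalibrationSpec) -> np.ndarray:
    ages = np.arange(spec.age_range[0], spec.age_range[1] + 1)
    years = np.arange(spec.year_range[0], spec.year_range[1] + 1)
    births = years[None, :] - ages[:, None]
    period = p ** (years - spec.base_year)
    cohort = c ** (births - spec.cohort_reference_year)
    return sched[ages][:, None] * period[None, :] * cohort


def loss(
    p: float,
    c: float,
    observed: pd.DataFrame,
    m1950: np.ndarray,
    spec: CalibrationSpec | None = None,
) -> float:
    """Sum of squared (log-)rate differences over the calibration grid."""
    spec = spec or CalibrationSpec()
    obs = observed.to_numpy(dtype=float)
    model = _surface_array(p, c, np.asarray(m1950, dtype=float), spec)
    if obs.shape != model.shape:
        raise CalibrationError(f"observed surface shape {obs.shape} != grid {model.shape}")
    if spec.scale == "log":
        if (obs <= 0).any():
            raise CalibrationError("log-scale loss requires strictly positive observed rates")
        resid = np.log(model) - np.log(obs)
    else:
        resid = model - obs
    return float(np.sum(resid**2))


def calibrate_sex(
    observed: pd.DataFrame,
    m1950: np.ndarray,
    spec: CalibrationSpec | None = None,
) -> tuple[float, float, float, int, bool]:
    """Fit (p, c) for one sex; returns (p, c, loss, iterations, converged)."""
    spec = spec or CalibrationSpec()
    sched = np.asarray(m1950, dtype=float)

    def objective(x: np.ndarray) -> float:
        return loss(x[0], x[1], observed, sched, spec)

    options = {"xatol": 1e-10, "fatol": spec.loss_tol * 1e-2, "maxiter": spec.max_iter}
    res = minimize(
        objective, np.asarray(spec.initial), method="Nelder-Mead", bounds=spec.bounds, options=options
    )
    # one restart at the incumbent tightens the simplex around the optimum
    res2 = minimize(objective, res.x, method="Nelder-Mead", bounds=spec.bounds, options=options)
    best = res2 if res2.fun <= res.fun else res
    iters = int(res.nit + res2.nit)
    converged = bool(res.success or res2.success)
    return float(best.x[0]), float(best.x[1]), float(best.fun), iters, converged


def calibrate(
    observed: dict[str, pd.DataFrame],
    m1950: dict[str, np.ndarray],
    spec: CalibrationSpec | None = None,
) -> CalibrationResult:
    """Independent per-sex fits of the period/cohort coefficients."""
    spec = spec or CalibrationSpec()
    result = CalibrationResult(p={}, c={}, loss={}, iterations={}, converged={})
    for sex in SEXES:
        p, c, fl, it, ok = calibrate_sex(observed[sex], m1950[sex], spec)
        result.p[sex], result.c[sex] = p, c
        result.loss[sex], result.iterations[sex], result.converged[sex] = fl, it, ok
    return result
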