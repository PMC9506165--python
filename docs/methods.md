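# Methods

## Scope and bookkeeping conventions

The model tracks Japanese-style postwar cohorts: 118 birth cohorts
(1880–1997) per sex, simulated annually over calendar years 1950–2017,
with results reported for ages 20–69. A row labelled year *t* is the state
at the start of *t*; flows occur during [t, t+1). Age in year *t* is
*t − birth year* (completed years at the start of *t*), so the 1880 cohort
is exactly at the exit age in 1950: it is instantiated — keeping the
118-cohort count — but contributes zero person-time. Cohorts born 1950 or
later enter at the start of their birth year with the year's birth count
and are exposed to the age-0 hazard that same year. The engine simulates
ages 0–69 (so that post-1950 cohorts age into adulthood correctly); all
excess-mortality reporting restricts to 20–69.

## Hazard model

Total mortality is multiplicative in age, period and cohort:
`m(a,t) = m1950(a) · p^(t−1950) · c^(b−1880)`, per sex. The cohort
reference year is fixed at 1880 (the earliest cohort). This convention is
shared by the synthetic generator and the calibrator; the classic APC
identifiability problem does not bite here because the age schedule
`m1950` is held fixed (taken from data, not refit), which pins *c* through
the age-diagonal structure of the surface.

The CVD share of deaths `prop(t)` varies by year but not by age (the
underlying cause-of-death tabulations do not resolve age), so
`h_cvd = m·prop(t)·M` and `h_other = m·(1−prop(t))`. Other-cause hazards
never see the salt multiplier and are therefore identical across
scenarios by construction.

## Salt effect

The dose–response anchor is: +10 mmol/day sodium (0.584 g salt) ↔ +1% CVD
mortality. The effect is split 1:1 between a period channel (assumed −
actual intake at the current year and age) and a cohort channel (the same
difference at the cohort's age 20), and applies only from age 20 on. The
default functional form is the power law

    M(Δp, Δc) = 1.01^((Δp/2 + Δc/2)/0.584),

chosen over the linear form `1 + 0.01·Δ/0.584` because it composes
exactly over the two channels (`M(Δp,Δc) = M(Δp,0)·M(0,Δc)`), remains
positive for arbitrarily large negative differences, and agrees with the
1%-per-unit statement exactly at one unit. The linear form is available
via `SaltEffectParams(form="linear")`; it is floored at zero to keep
hazards valid.

## Exposure surface reconstruction

Survey constraints shape the procedure: overall means only for 1973–1994,
sex × 10-year-group means for 1995–2017.

* Back-cast: an OLS line through the overall series on 1973–1986 (the
  window where the trend is nearly linear) is evaluated for
  1900–1972. The surface starts at 1900 — not 1950 — because the cohort
  channel needs each cohort's intake at age 20 and the oldest cohort
  turned 20 in 1900. Male values in 1942 and earlier are capped at
  20 g/day (pre-war dietary records); the cap is enforced both on the
  overall back-cast and cell-wise on the assembled male surface, so no
  male pre-1943 cell exceeds 20 g/day even in age groups that run above
  the overall mean. Females are used as fitted: the ceiling is a
  male-specific pre-war observation.
* Age gradient: per sex and 10-year group, the ratio of the group's
  1995–2017 mean to the overall 1995–2017 mean. The survey does not
  publish an overall series after 1994, so the reference overall is the
  unweighted mean of the group means in each year; the ratios then average
  exactly 1 across groups, making the construction self-consistent.
  Groups are 20–29 … 60–69 plus an open group below 20; single ages share
  their group's value, and ages below 20 take the youngest group's value —
  inert for results, since the salt effect is switched off below age 20.
* 1973–1994 published overall values are used as published (no smoothing);
  1995–2017 group values pass through unchanged.

Counterfactuals move each post-1950 cell toward its 1950 value:
`assumed(t) = actual(t) + (1−f)(actual(1950) − actual(t))`. `f = 1`
returns the identical surface object (bitwise), which makes the base-run
identity an exact, not approximate, property. The assumed salt-at-20
series is recomputed from the assumed surface, so cohorts who turned 20
before 1950 are untouched in both channels.

## Cohort stepping

The annual update is the exact constant-hazard competing-risks step:
survivors `= N·exp(−h)`, deaths `= N·(1−exp(−h))` allocated in proportion
`h_cvd : h_other`. Compared with a small-dt Euler scheme this removes the
integration step as a tuning parameter and is robust for the large
early-century hazards (the synthetic 1950 schedule reaches ~0.02 at birth
and ~0.02 at age 69); for small hazards the two agree to first order.
Deaths are computed from start-of-year stocks; aging out happens after
deaths in the year the cohort is aged 69. Per-cohort conservation
(entry stock = all flows + terminal survivors) holds to ~1e-12 relative
and is asserted at 1e-9.

## Calibration

Per sex, (p, c) minimise the unweighted sum of squared log-rate residuals
over the full age 0–69 × year 1950–2017 grid. Log scale keeps the young
ages — two orders of magnitude below the old — from being ignored; a
linear-scale option exists. The optimizer is Nelder–Mead from (1, 1)
inside [0.8, 1.2]², restarted once at its own optimum (tightens the final
simplex), iteration cap 2000. The full calibration grid uses ages 0–69
rather than 20–69 because the life-table surface covers the full span and
the extra rows sharpen the cohort coefficient. On noiseless
self-generated surfaces the routine recovers generating truths to ~1e-8;
the tested guarantee is 1e-4 across a grid of truths and 1e-3 under 1%
multiplicative log-normal noise.

## Synthetic data generator

The generator emulates the structure, not the values, of the real
sources:

* 1950 pyramid: exponential taper `base·exp(−0.028·age)` with base
  1.05 M (men) / 1.00 M (women) per single age — a working-age-heavy
  postwar pyramid of ~64 M persons under 71.
* births: 1.5 M/year total in 1950 declining 1 %/year, male fraction
  0.512.
* 1950 mortality: Gompertz `5e-5·exp(0.085·age)` plus an infant offset of
  0.02 at age 0; female rates scaled by 0.85.
* CVD share: 0.20 in 1950 rising linearly to 0.40 by 1970, easing back to
  0.30 by 2017 — the rise-then-fall of the cardiovascular share of deaths.
* salt: overall paths linear from 20 → 12 g/day (men) and 14 → 9.6
  (women) over 1950–1994, then to 11 / 9 by 2017; extended backwards along
  the 1950–1994 slope and clamped at 25 g/day. Age gradient: fixed group
  ratios (young-adult trough ≈ 0.9, mid-age peak ≈ 1.1, normalised to
  mean 1) applied multiplicatively. Surveys publish this truth exactly in
  the historical formats (overall 1973–1994; groups 1995–2017).
* observed mortality: the APC model surface at the ground-truth (p, c) —
  by default the coefficient pairs the calibration is expected to
  recover — optionally with `exp(N(0, σ²))` noise per cell; σ = 0 by
  default so the primary pipeline is deterministic, and all randomness
  flows from a single `numpy.random.default_rng(seed)`.

Because the pre-1973 truth is linear by construction and the group ratios
are year-constant, the imputation reconstructs the true surface
essentially exactly over 1950–1994 (tested bound: MAE ≤ 0.5 g/day); the
deliberate mismatch is pre-1943 male intake, where the truth runs up to
25 g/day but the imputation caps at 20. What passing tests show is that
the pipeline's machinery is correct under these idealised conditions;
they do not show that real NHNS data are linear pre-1973, that real group
ratios are time-constant, or that real mortality follows the two-
coefficient APC form. Headline quantities for Japan (e.g. accumulated
excess deaths) therefore cannot be reproduced here: they require the
actual government input series, which are not redistributable through
this package. The analysis reports those quantities for the synthetic
world and checks their qualitative shape (positive, growing relative
excess; late-peaking, plateauing male absolute excess; near-linearity of
accumulated excess in the retained fraction, within 10%).

## Numerical notes and limitations

* Excess mortality is computed on death counts, so population feedback is
  included: a counterfactual's extra deaths shrink its later stocks, which
  is why accumulated excess is only *near*-linear in (1 − f).
* Relative excess uses the base run's CVD deaths as denominator; years
  with zero base deaths (not reachable with positive inputs) report 0.
* `h = 0` steps allocate zero deaths without division; scenario fraction
  f = 1 short-circuits to an identical-surface copy so the base-run
  identity is bitwise.
* No migration, no sub-annual seasonality, no stochastic individual-level
  variation; the salt–mortality effect is not modified by age, sex, or
  blood pressure; salt has no effect on non-CVD mortality in this model.
* Problem sizes: all analyses run on the full 2 × 118 × 68 cohort-year
  grid; calibration evaluates a 70 × 68 surface per loss call and
  converges in ~140 simplex iterations per sex.
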