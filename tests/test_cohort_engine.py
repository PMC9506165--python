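"""Stock-flow cohort simulator: the annual step, initialisation, full runs."""

import numpy as np
import pandas as pd
import pytest

import saltcvd as sc


class TestStepCohort:
    def make_state(self, pop=1000.0, birth=1930, year=1970):
        return sc.CohortState(birth_year=birth, sex="male", current_year=year, population=pop)

    def test_zero_hazard_is_inert(self):
        nxt, flows = sc.step_cohort(self.make_state(), 0.0, 0.0)
        assert nxt.population == 1000.0
        assert flows.cvd_deaths == flows.other_deaths == flows.aged_out == 0.0

    def test_competing_risks_closed_form(self):
        nxt, flows = sc.step_cohort(self.make_state(), 0.01, 0.01)
        assert nxt.population == pytest.approx(1000 * np.exp(-0.02), rel=1e-12)
        assert nxt.population == pytest.approx(980.199, abs=1e-3)
        assert flows.cvd_deaths == pytest.approx(9.9007, abs=1e-4)
        assert flows.other_deaths == pytest.approx(flows.cvd_deaths, rel=1e-12)

    def test_unequal_hazards_allocate_proportionally(self):
        _, flows = sc.step_cohort(self.make_state(), 0.03, 0.01)
        assert flows.cvd_deaths == pytest.approx(3 * flows.other_deaths, rel=1e-12)

    def test_age69_survivors_age_out(self):
        state = self.make_state(birth=1901, year=1970)  # age 69
        nxt, flows = sc.step_cohort(state, 0.01, 0.01)
        assert flows.aged_out == pytest.approx(1000 * np.exp(-0.02), rel=1e-12)
        assert nxt.population == 0.0
        assert not nxt.active

    def test_negative_hazard_rejected(self):
        with pytest.raises(sc.ValidationError):
            sc.step_cohort(self.make_state(), -0.01, 0.0)


class TestInitCohorts:
    def test_entry_stocks(self, bundle):
        cfg = sc.RunConfig()
        cohorts = sc.init_cohorts(bundle.demography, cfg)
        by_birth = {s.birth_year: s for s in cohorts["male"]}
        assert len(cohorts["male"]) == cfg.n_cohorts
        # census cohort: 1950 stock at its 1950 age
        assert by_birth[1930].population == bundle.demography.initial_population.at[20, "male"]
        assert by_birth[1930].current_year == 1950
        # birth cohort: birth count in its birth year
        assert by_birth[1960].population == bundle.demography.births.at[1960, "male"]
        assert by_birth[1960].current_year == 1960
        # the oldest cohort is at the exit age from the start: zero person-time
        assert not by_birth[cfg.min_cohort_year].active


def toy_world(p=1.0, c=1.0, prop=0.3, hazard0=0.05, hazard_slope=0.02):
    """A 4-cohort, 2-year world small enough to check by hand."""
    cfg = sc.RunConfig(
        start_year=1950, end_year=1951, adult_age=1, exit_age=3, scenario_fractions=(1.0,)
    )
    ages = np.arange(0, cfg.exit_age + 1)
    pop = pd.DataFrame({s: 1000.0 * (4 - ages) for s in sc.SEXES}, index=ages)
    births = pd.DataFrame({s: [500.0] for s in sc.SEXES}, index=[1950])
    m = np.array([hazard0 + hazard_slope * a for a in range(cfg.exit_age)])
    observed = {
        s: pd.DataFrame(
            np.tile(m[:, None], (1, 2)), index=np.arange(cfg.exit_age), columns=[1950, 1951]
        )
        for s in sc.SEXES
    }
    demo = sc.DemographyInputs(pop, births, observed, cfg).validate()
    params = sc.APCParams(
        m1950={s: m for s in sc.SEXES},
        p=dict.fromkeys(sc.SEXES, p),
        c=dict.fromkeys(sc.SEXES, c),
        cvd_proportion=pd.Series(prop, index=[1950, 1951]),
        cohort_reference_year=cfg.min_cohort_year,
        base_year=1950,
    ).validate()
    salt_df = {
        s: pd.DataFrame(10.0, index=np.arange(cfg.exit_age), columns=[1950, 1951])
        for s in sc.SEXES
    }
    at20 = {s: pd.Series(10.0, index=cfg.cohorts) for s in sc.SEXES}
    salt = sc.SaltExposureSurface(salt=salt_df, salt_at_20=at20)
    return cfg, demo, params, salt


class TestRunModel:
    def test_two_year_toy_matches_hand_stepping(self):
        cfg, demo, params, salt = toy_world()
        res = sc.run_model(demo, params, salt, salt, cfg)
        prop = 0.3
        # cohort 1949 enters 1950 at age 1 with the census stock for age 1
        state = sc.CohortState(1949, "male", 1950, 3000.0, cfg.exit_age, cfg.end_year)
        ledger = {}
        for year, age in ((1950, 1), (1951, 2)):
            h = params.m1950["male"][age]
            state, flows = sc.step_cohort(state, h * prop, h * (1 - prop))
            ledger[year] = flows
        ci = int(np.flatnonzero(res.cohorts == 1949)[0])
        for ti, year in enumerate(res.years):
            assert res.cvd_deaths["male"][ti, ci] == pytest.approx(
                ledger[year].cvd_deaths, rel=1e-12
            )
            assert res.other_deaths["male"][ti, ci] == pytest.approx(
                ledger[year].other_deaths, rel=1e-12
            )
        # age 2 is the last year before the exit age: survivors age out
        assert res.aged_out["male"][1, ci] == pytest.approx(ledger[1951].aged_out, rel=1e-12)
        assert res.aged_out["male"][1, ci] > 0

    def test_birth_cohort_enters_with_birth_count(self):
        cfg, demo, params, salt = toy_world()
        res = sc.run_model(demo, params, salt, salt, cfg)
        ci = int(np.flatnonzero(res.cohorts == 1950)[0])
        assert res.population["male"][0, ci] == 500.0
        # exposed to the age-0 hazard in its birth year
        assert res.cvd_deaths["male"][0, ci] > 0

    def test_equal_surfaces_reproduce_base_run_exactly(self, bundle, params, surface):
        base = sc.run_model(bundle.demography, params, surface, surface, scenario="a")
        again = sc.run_model(
            bundle.demography, params, surface, sc.counterfactual_salt(surface, 1.0), scenario="b"
        )
        for sex in sc.SEXES:
            assert np.array_equal(base.cvd_deaths[sex], again.cvd_deaths[sex])
            assert np.array_equal(base.population[sex], again.population[sex])

    def test_linearity_in_population(self, bundle, params, surface):
        demo = bundle.demography
        doubled = sc.DemographyInputs(
            demo.initial_population * 2.0,
            demo.births * 2.0,
            demo.observed_mortality,
            demo.config,
        ).validate()
        r1 = sc.run_model(demo, params, surface, surface)
        r2 = sc.run_model(doubled, params, surface, surface)
        for sex in sc.SEXES:
            np.testing.assert_allclose(r2.cvd_deaths[sex], 2 * r1.cvd_deaths[sex], rtol=1e-12)
            np.testing.assert_allclose(r2.aged_out[sex], 2 * r1.aged_out[sex], rtol=1e-12)

    def test_no_person_time_outside_scope(self, scenario_results):
        """No stock at ages >= 70 and none before a cohort's entry year."""
        res = scenario_results["base"]
        ages = res.years[:, None] - res.cohorts[None, :]
        outside = (ages < 0) | (ages >= 70)
        for sex in sc.SEXES:
            assert res.population[sex][outside].sum() == 0.0
            assert res.cvd_deaths[sex][outside].sum() == 0.0

    def test_per_cohort_conservation(self, scenario_results, bundle):
        """Entry stock = all flows + terminal survivors, per cohort and sex."""
        res = scenario_results["base"]
        demo = bundle.demography
        for sex in sc.SEXES:
            flows = (
                res.cvd_deaths[sex].sum(axis=0)
                + res.other_deaths[sex].sum(axis=0)
                + res.aged_out[sex].sum(axis=0)
            )
            last = res.population[sex][-1, :]
            terminal = last - (
                res.cvd_deaths[sex][-1, :] + res.other_deaths[sex][-1, :] + res.aged_out[sex][-1, :]
            )
            for ci, b in enumerate(res.cohorts):
                if b < 1950:
                    age = 1950 - b
                    entry = (
                        float(demo.initial_population.at[age, sex]) if age < 70 else 0.0
                    )
                else:
                    entry = float(demo.births.at[b, sex])
                total = flows[ci] + terminal[ci]
                assert total == pytest.approx(entry, rel=1e-9), f"cohort {b} ({sex})"
            assert (terminal >= -1e-9 * np.maximum(last, 1)).all()

    def test_stock_recursion_is_exact(self, scenario_results):
        res = scenario_results["base"]
        for sex in sc.SEXES:
            pop = res.population[sex]
            expected_next = (
                pop - res.cvd_deaths[sex] - res.other_deaths[sex] - res.aged_out[sex]
            )
            ages_next = (res.years[:, None] + 1) - res.cohorts[None, :]
            carried = (ages_next >= 1) & (ages_next < 70) & (res.cohorts[None, :] <= res.years[:, None])
            np.testing.assert_allclose(
                pop[1:][carried[:-1]], expected_next[:-1][carried[:-1]], rtol=1e-9, atol=1e-9
            )
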