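"""Salt-surface reconstruction: back-cast, ratios, assembly, counterfactuals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import saltcvd as sc
from saltcvd import salt_exposure as se


def make_series(points: dict[int, float]) -> pd.Series:
    return pd.Series(points).sort_index()


class TestBackcastLine:
    def test_two_point_line(self):
        slope, intercept = se.fit_backcast_line(
            make_series({1973: 14.0, 1986: 12.7}), (1973, 1986)
        )
        assert slope == pytest.approx(-0.1, abs=1e-12)
        assert intercept + slope * 1950 == pytest.approx(16.3, abs=1e-9)

    def test_constant_series(self):
        slope, intercept = se.fit_backcast_line(
            make_series({y: 12.0 for y in range(1973, 1987)}), (1973, 1986)
        )
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(12.0, abs=1e-9)

    def test_exact_line_recovered(self):
        series = make_series({y: 30.0 - 0.15 * (y - 1900) for y in range(1973, 1995)})
        slope, _ = se.fit_backcast_line(series, (1973, 1986))
        assert slope == pytest.approx(-0.15, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(se.ImputationError):
            se.fit_backcast_line(make_series({1973: 14.0}), (1973, 1986))


class TestBackcastCap:
    cfg = se.ImputationConfig()

    def line_through(self, year: int, value: float, slope: float):
        return (slope, value - slope * year)

    def test_male_capped_at_20_in_1942_and_earlier(self):
        line = self.line_through(1940, 20.5, -0.1)
        vals = se.backcast_overall(line, range(1935, 1951), "male", self.cfg)
        assert vals.loc[1940] == 20.0
        assert (vals.loc[:1942] <= 20.0).all()

    def test_cap_inactive_after_1942(self):
        line = self.line_through(1950, 18.0, -0.1)
        vals = se.backcast_overall(line, range(1943, 1951), "male", self.cfg)
        assert vals.loc[1950] == pytest.approx(18.0)
        # same line pushed above 20 post-1942 stays uncapped
        hot = self.line_through(1945, 20.5, -0.1)
        assert se.backcast_overall(hot, [1945], "male", self.cfg).loc[1945] == 20.5

    def test_female_uncapped(self):
        line = self.line_through(1940, 21.0, -0.1)
        assert se.backcast_overall(line, [1940], "female", self.cfg).loc[1940] == 21.0

    def test_nonpositive_value_rejected(self):
        line = self.line_through(1940, -1.0, 0.0)
        with pytest.raises(se.ImputationError):
            se.backcast_overall(line, [1940], "female", self.cfg)


def group_table(values: dict[str, dict[tuple[int, int], float]], years) -> pd.DataFrame:
    rows = []
    for sex, groups in values.items():
        for (lo, hi), v in groups.items():
            for y in years:
                rows.append(
                    {"sex": sex, "year": y, "age_group_start": lo, "age_group_end": hi, "grams_per_day": v}
                )
    return pd.DataFrame(rows)


class TestGroupRatios:
    years = range(1995, 2018)

    def overall(self, value: float):
        return {s: pd.Series(value, index=list(self.years)) for s in sc.SEXES}

    def test_direct_ratio(self):
        groups = group_table(
            {s: {(40, 49): 13.2, (20, 29): 10.8} for s in sc.SEXES}, self.years
        )
        ratios = se.group_ratios(groups, self.overall(12.0))
        assert ratios["male"][(40, 49)] == pytest.approx(1.1)
        assert ratios["female"][(20, 29)] == pytest.approx(0.9)

    def test_identical_groups_give_unit_ratios(self):
        groups = group_table({s: {g: 12.0 for g in se.AGE_GROUPS} for s in sc.SEXES}, self.years)
        ratios = se.group_ratios(groups, self.overall(12.0))
        assert all(r == pytest.approx(1.0) for sx in ratios.values() for r in sx.values())

    def test_scale_invariance(self):
        groups = group_table({s: {(40, 49): 13.2} for s in sc.SEXES}, self.years)
        r1 = se.group_ratios(groups, self.overall(12.0))
        scaled = groups.assign(grams_per_day=groups["grams_per_day"] * 3.0)
        r2 = se.group_ratios(scaled, self.overall(36.0))
        assert r1["male"][(40, 49)] == pytest.approx(r2["male"][(40, 49)], rel=1e-12)


class TestBuildMatrix:
    def test_scaled_early_years_and_pass_through(self, bundle, surface):
        # 1980 cell = overall x ratio; within-group single ages share it
        male = surface.salt["male"]
        group_vals = male.loc[40:49, 1980].to_numpy()
        assert np.allclose(group_vals, group_vals[0])
        # 1995-2017 cells equal the survey group values exactly
        sub = bundle.salt_by_group
        row = sub[(sub.sex == "male") & (sub.year == 2000) & (sub.age_group_start == 40)]
        assert male.at[45, 2000] == pytest.approx(float(row.grams_per_day.iloc[0]), abs=1e-12)

    def test_direct_arithmetic(self):
        overall = {s: pd.Series({1980: 12.0}) for s in sc.SEXES}
        ratios = {s: {g: (1.1 if g == (40, 49) else 1.0) for g in se.AGE_GROUPS} for s in sc.SEXES}
        groups = group_table({s: {g: 10.0 for g in se.AGE_GROUPS} for s in sc.SEXES}, [1995])
        surf = se.build_salt_matrix(overall, ratios, groups)
        assert surf["male"].at[45, 1980] == pytest.approx(13.2)
        assert surf["male"].at[45, 1995] == pytest.approx(10.0)

    def test_group_window_means_recover_survey_values(self, bundle, surface):
        """Averaging the built surface over the reference window returns the
        survey group means for 1995-2017 (they are passed through)."""
        sub = bundle.salt_by_group
        for sex in sc.SEXES:
            df = surface.salt[sex]
            for (lo, hi) in se.AGE_GROUPS:
                got = df.loc[lo:hi, 1995:2017].mean().mean()
                want = sub[
                    (sub.sex == sex) & (sub.age_group_start == lo) & (sub.year >= 1995)
                ]["grams_per_day"].mean()
                assert got == pytest.approx(want, rel=1e-12)


class TestSaltAt20:
    def test_index_mapping(self, surface):
        for sex in sc.SEXES:
            assert surface.salt_at_20[sex].loc[1975] == surface.value(sex, 1995, 20)
            assert surface.salt_at_20[sex].loc[1997] == surface.value(sex, 2017, 20)

    def test_prewar_cohort_uses_capped_backcast(self, surface):
        assert surface.salt_at_20["male"].loc[1920] == surface.value("male", 1940, 20)
        assert surface.salt_at_20["male"].loc[1920] <= 20.0

    def test_missing_year_is_an_error(self, surface):
        with pytest.raises(se.ImputationError):
            se.salt_at_age20(surface.salt, cohorts=[1870])


class TestCounterfactual:
    def test_base_fraction_is_bitwise_identity(self, surface):
        assumed = sc.counterfactual_salt(surface, 1.0)
        for sex in sc.SEXES:
            assert np.array_equal(assumed.salt[sex].to_numpy(), surface.salt[sex].to_numpy())
            assert np.array_equal(
                assumed.salt_at_20[sex].to_numpy(), surface.salt_at_20[sex].to_numpy()
            )

    def test_zero_fraction_freezes_anchor_level(self, surface):
        assumed = sc.counterfactual_salt(surface, 0.0)
        for sex in sc.SEXES:
            df = assumed.salt[sex]
            anchor = surface.salt[sex][1950]
            for year in (1950, 1990, 2017):
                pd.testing.assert_series_equal(df[year], anchor, check_names=False)

    def test_half_fraction_arithmetic(self, surface):
        f = 0.5
        assumed = sc.counterfactual_salt(surface, f)
        act = surface.value("male", 1990, 45)
        anchor = surface.value("male", 1950, 45)
        assert assumed.value("male", 1990, 45) == pytest.approx(
            act + (1 - f) * (anchor - act), rel=1e-12
        )

    def test_pre_anchor_years_untouched(self, surface):
        assumed = sc.counterfactual_salt(surface, 0.0)
        for sex in sc.SEXES:
            pre = [y for y in surface.salt[sex].columns if y < 1950]
            pd.testing.assert_frame_equal(assumed.salt[sex][pre], surface.salt[sex][pre])
            # cohorts turning 20 before 1950 keep their actual intake at 20
            old = surface.salt_at_20[sex].loc[:1929]
            pd.testing.assert_series_equal(assumed.salt_at_20[sex].loc[:1929], old)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        f1=st.floats(0.0, 1.0, allow_nan=False),
        f2=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_monotone_in_fraction_for_declining_salt(self, declining_surface, f1, f2):
        """With salt declining after the anchor, a smaller retained fraction
        means more (never less) assumed salt at every cell."""
        lo, hi = sorted((f1, f2))
        a_lo = sc.counterfactual_salt(declining_surface, lo)
        a_hi = sc.counterfactual_salt(declining_surface, hi)
        for sex in sc.SEXES:
            assert (
                a_lo.salt[sex].to_numpy() >= a_hi.salt[sex].to_numpy() - 1e-12
            ).all()

    def test_fraction_out_of_range_rejected(self, surface):
        with pytest.raises(sc.ValidationError):
            sc.counterfactual_salt(surface, 1.5)


@pytest.fixture(scope="module")
def declining_surface(surface):
    return surface
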