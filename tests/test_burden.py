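"""PIF/DPP/YLL/YPLL engine and the run_model orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tfamm.burden import (
    EconParams,
    LifeTable,
    MortalityRecord,
    aggregate_paf,
    dpp,
    pif,
    productive_years,
    run_model,
    yll,
    ypll_and_cost,
)
from tfamm.errors import ConfigError, InputError
from tfamm.exposure import (
    BinGrid,
    ExposureDistribution,
    discretize_lognormal,
    null_scenario,
)
from tfamm.fixtures import SyntheticConfig, make_synthetic_bundle
from tfamm.risk import AGE_GROUPS, CHD, RRCurve, RRSpec, build_rr_curve


def two_bin_setup():
    """Tiny 2-bin world for hand arithmetic."""
    grid = BinGrid(width=1.0, n_bins=2, top_midpoint=1.5)
    curve = RRCurve(CHD, "25-34", grid, np.array([1.0, 1.42]))
    mk = lambda p: ExposureDistribution(
        grid=grid, prevalence=np.array(p), mean_pct_energy=0.5, cv=0.5
    )
    return grid, curve, mk


class TestPIF:
    def test_identical_distributions_give_zero(self):
        _, curve, mk = two_bin_setup()
        assert pif(mk([0.5, 0.5]), mk([0.5, 0.5]), curve) == 0.0

    def test_two_bin_hand_value(self):
        # (0.5*1 + 0.5*1.42 - 1) / (0.5*1 + 0.5*1.42) = 0.21/1.21
        _, curve, mk = two_bin_setup()
        assert pif(mk([0.5, 0.5]), mk([1.0, 0.0]), curve) == pytest.approx(
            0.21 / 1.21, rel=1e-12
        )

    def test_zero_counterfactual_equals_paf(self, grid):
        """Shifting all mass to the first bin (RR=1) maximizes the impact
        fraction: PIF == PAF == 1 - 1/mean(RR)."""
        base = discretize_lognormal(0.68, 0.5, grid)
        cf = discretize_lognormal(0.0, 0.5, grid)
        curve = build_rr_curve(RRSpec(CHD, "25-34", 1.42, 1.28, 1.57), grid)
        expected = 1.0 - 1.0 / float(curve.rr_by_bin @ base.prevalence)
        assert pif(base, cf, curve) == pytest.approx(expected, rel=1e-12)

    def test_grid_mismatch_rejected(self, grid):
        base = discretize_lognormal(0.68, 0.5, grid)
        other = BinGrid(width=0.2, n_bins=13, top_midpoint=2.5)
        cf = discretize_lognormal(0.3, 0.5, other)
        curve = build_rr_curve(RRSpec(CHD, "25-34", 1.42, 1.28, 1.57), grid)
        with pytest.raises(ConfigError):
            pif(base, cf, curve)

    @given(
        mean_base=st.floats(0.1, 1.2),
        reduction=st.floats(0.0, 1.0),
        cv=st.floats(0.2, 0.8),
    )
    def test_dominance(self, mean_base, reduction, cv):
        """Counterfactual stochastically below baseline with RR >= 1
        everywhere implies 0 <= PIF <= 1."""
        base = discretize_lognormal(mean_base, cv)
        cf = discretize_lognormal(mean_base * (1 - reduction), cv)
        curve = build_rr_curve(RRSpec(CHD, "25-34", 1.42, 1.28, 1.57))
        value = pif(base, cf, curve)
        assert -1e-12 <= value <= 1.0


class TestDPPAndAggregation:
    def test_dpp_arithmetic(self):
        rec = MortalityRecord(CHD, "male", "40-44", 500.0)
        assert dpp(0.0, MortalityRecord(CHD, "male", "40-44", 1000.0)) == 0.0
        assert dpp(0.1, rec) == pytest.approx(50.0)

    def test_dpp_never_exceeds_deaths(self):
        rec = MortalityRecord(CHD, "male", "40-44", 500.0)
        assert dpp(1.0, rec) == 500.0
        with pytest.raises(InputError):
            dpp(1.5, rec)

    def test_aggregate_paf_weighted_mean(self):
        assert aggregate_paf([(0.2, 100.0), (0.0, 300.0)]) == pytest.approx(
            20.0 / 400.0
        )
        assert aggregate_paf([(0.3, 50.0)]) == pytest.approx(0.3)

    @given(p=st.floats(0.0, 1.0),
           deaths=st.lists(st.floats(1.0, 1e4), min_size=1, max_size=8))
    def test_aggregate_of_constant_pif_is_that_pif(self, p, deaths):
        assert aggregate_paf([(p, d) for d in deaths]) == pytest.approx(p)

    def test_all_zero_deaths_undefined(self):
        with pytest.raises(InputError):
            aggregate_paf([(0.2, 0.0), (0.1, 0.0)])


class TestLifeYearsAndCosts:
    def life_table(self):
        return LifeTable(dict(zip(
            AGE_GROUPS, np.linspace(50.0, 7.0, len(AGE_GROUPS)))))

    def econ(self, wage=7000.0):
        return EconParams(
            mean_annual_wage=wage,
            lfpr={(s, a): 0.8 for s in ("male", "female")
                  for a in AGE_GROUPS},
        )

    def test_yll_is_deaths_times_expectancy(self):
        lt = LifeTable({"40-44": 20.0})
        assert yll(10.0, "40-44", lt) == 200.0
        assert yll(0.0, "40-44", lt) == 0.0

    def test_missing_life_table_entry_is_config_error(self):
        with pytest.raises(ConfigError):
            yll(1.0, "80+", LifeTable({"40-44": 20.0}))

    def test_life_table_must_be_non_increasing(self):
        with pytest.raises(InputError):
            LifeTable({"25-29": 30.0, "30-34": 35.0})

    def test_ypll_example_male_40(self):
        # midpoint age 42.5 -> 22.5 productive years to pension at 65
        years, cost = ypll_and_cost(1.0, "male", "40-44", self.econ())
        assert years == pytest.approx(65.0 - 42.5)
        assert cost == pytest.approx(22.5 * 7000.0 * 0.8)

    def test_death_at_or_past_pension_age_costs_nothing(self):
        for age in ("65-69", "80+"):
            years, cost = ypll_and_cost(5.0, "male", age, self.econ())
            assert years == 0.0 and cost == 0.0
        # female pension age is 60: the 60-64 stratum is already retired
        years, cost = ypll_and_cost(5.0, "female", "60-64", self.econ())
        assert years == 0.0 and cost == 0.0

    def test_missing_lfpr_entry_is_config_error(self):
        econ = EconParams(mean_annual_wage=1.0,
                          lfpr={("male", "25-29"): 0.9})
        with pytest.raises(ConfigError):
            ypll_and_cost(1.0, "female", "25-29", econ)


class TestRunModel:
    def test_null_scenario_gives_zero_burden(self):
        syn = make_synthetic_bundle(SyntheticConfig(seed=1))
        result = run_model(syn.bundle, null_scenario())
        for col in ("pif", "dpp", "yll", "ypll", "cost"):
            assert float(result.strata[col].abs().sum()) == 0.0

    def test_totals_are_sums_of_strata(self):
        syn = make_synthetic_bundle(SyntheticConfig(seed=2))
        result = run_model(syn.bundle, syn.scenarios["ban"])
        for col in ("dpp", "yll", "ypll", "cost"):
            by_outcome = result.by("outcome", col).sum()
            by_sex = result.by("sex", col).sum()
            assert result.total(col) == pytest.approx(by_outcome)
            assert result.total(col) == pytest.approx(by_sex)

    def test_dpp_bounded_by_deaths_in_every_stratum(self):
        syn = make_synthetic_bundle(SyntheticConfig(seed=3))
        result = run_model(syn.bundle, syn.scenarios["ban"])
        assert (result.strata["dpp"] <= result.strata["deaths"] + 1e-9).all()
        assert (result.strata["dpp"] >= 0).all()

    def test_covers_every_stratum(self):
        syn = make_synthetic_bundle(SyntheticConfig(seed=4))
        result = run_model(syn.bundle, syn.scenarios["cap"])
        assert len(result.strata) == 2 * 2 * len(AGE_GROUPS)

    def test_ypll_bounded_by_yll_where_pension_before_expectancy(
            self, brazil):
        """Productive years lost cannot exceed life years lost in strata
        where the pension age falls within the expected remaining life."""
        result = run_model(brazil.bundle, brazil.scenarios["C"])
        lt = brazil.bundle.life_table
        pension = brazil.bundle.econ.pension_age
        from tfamm.risk import midpoint_age

        for row in result.strata.itertuples():
            a = midpoint_age(row.age_group)
            if pension[row.sex] <= a + lt.residual(row.age_group):
                assert row.ypll <= row.yll + 1e-9

    def test_missing_rr_band_is_config_error(self):
        syn = make_synthetic_bundle(SyntheticConfig(seed=5))
        table = {k: v for k, v in syn.bundle.rr_table.items()
                 if k[1] != "75+"}
        with pytest.raises(ConfigError):
            run_model(syn.bundle, syn.scenarios["ban"], rr_table=table)
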