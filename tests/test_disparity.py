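"""Gap filling, population-weighted exposure, and disparity metrics."""

import numpy as np
import pandas as pd
import pytest

from airburden.containers import ConcentrationField, PopulationGrid
from airburden.disparity import (
    gap_fill,
    gap_fill_sensitivity,
    population_weighted_exposure,
    relative_disparity,
    subgroup_burden_rate,
)
from airburden.grids import GridDefinition
from airburden.rates import RateTable


def _rate_rows(entries):
    rows = []
    for level, region, state, subgroup, rate, suppressed in entries:
        rows.append(
            {
                "level": level,
                "region_id": region,
                "state_id": state,
                "cause": "mortality",
                "age_group": "age_standardized",
                "subgroup": subgroup,
                "rate": np.nan if suppressed else rate,
                "suppressed": suppressed,
                "provenance": level,
            }
        )
    return RateTable(pd.DataFrame(rows))


class TestGapFill:
    def test_fully_populated_table_unchanged(self):
        rt = _rate_rows(
            [
                ("county", "c0", "s0", "total", 700.0, False),
                ("county", "c0", "s0", "black", 800.0, False),
                ("state", "s0", "s0", "total", 720.0, False),
                ("national", "US", "US", "total", 710.0, False),
            ]
        )
        filled, log = gap_fill(rt)
        assert len(log) == 0
        pd.testing.assert_frame_equal(filled.table, rt.table)

    def test_county_subgroup_falls_back_to_county_total(self):
        rt = _rate_rows(
            [
                ("county", "c0", "s0", "total", 700.0, False),
                ("county", "c0", "s0", "black", None, True),
                ("state", "s0", "s0", "total", 720.0, False),
                ("state", "s0", "s0", "black", 820.0, False),
                ("national", "US", "US", "total", 710.0, False),
            ]
        )
        filled, log = gap_fill(rt)
        row = filled.select(level="county", region_id="c0", subgroup="black").iloc[0]
        assert row["rate"] == 700.0  # county-total preferred over state-subgroup
        assert row["provenance"] == "gap-filled:county_total"
        assert log.iloc[0]["source"] == "county_total"

    def test_county_total_falls_back_to_state(self):
        rt = _rate_rows(
            [
                ("county", "c0", "s0", "total", None, True),
                ("state", "s0", "s0", "total", 720.0, False),
                ("national", "US", "US", "total", 710.0, False),
            ]
        )
        filled, _ = gap_fill(rt)
        row = filled.select(level="county", region_id="c0", subgroup="total").iloc[0]
        assert row["rate"] == 720.0
        assert row["provenance"] == "gap-filled:state_total"

    def test_degenerate_cascade_reaches_national(self):
        rt = _rate_rows(
            [
                ("county", "c0", "s0", "black", None, True),
                ("national", "US", "US", "total", 710.0, False),
            ]
        )
        filled, _ = gap_fill(rt)
        row = filled.select(level="county", region_id="c0", subgroup="black").iloc[0]
        assert row["rate"] == 710.0
        assert row["provenance"] == "gap-filled:national_total"

    def test_state_subgroup_preferred_over_state_total(self):
        rt = _rate_rows(
            [
                ("county", "c0", "s0", "black", None, True),
                ("state", "s0", "s0", "total", 720.0, False),
                ("state", "s0", "s0", "black", 820.0, False),
                ("national", "US", "US", "total", 710.0, False),
            ]
        )
        filled, log = gap_fill(rt)
        row = filled.select(level="county", region_id="c0", subgroup="black").iloc[0]
        assert row["rate"] == 820.0
        assert log.iloc[0]["source"] == "state_subgroup"

    def test_missing_national_fallback_rejected(self):
        rt = _rate_rows([("county", "c0", "s0", "black", None, True)])
        with pytest.raises(ValueError, match="no fallback"):
            gap_fill(rt)

    def test_generated_table_fully_resolves(self, rate_table):
        filled, log = gap_fill(rate_table)
        assert not filled.has_suppressed()
        assert len(log) == rate_table.n_suppressed()


class TestPopulationWeightedExposure:
    def test_uniform_field_returns_constant_for_every_subgroup(self, population):
        conc = np.full(population.grid.shape, 3.7)
        for sub in population.subgroups:
            if population.total_persons(sub) > 0:
                assert population_weighted_exposure(conc, population, sub) == pytest.approx(3.7)

    def test_matches_brute_force_weighted_mean(self, population, scenario_set):
        conc = scenario_set.baseline["PM2.5"].values
        w = population.counts[population.subgroup_index("black")].sum(axis=0)
        expected = (conc * w).sum() / w.sum()
        got = population_weighted_exposure(conc, population, "black")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_population_flagged_not_zero(self, grid):
        pop = PopulationGrid(
            grid=grid,
            age_bins=[(0.0, 100.0)],
            subgroups=["total", "empty"],
            counts=np.concatenate(
                [np.ones((1, 1) + grid.shape), np.zeros((1, 1) + grid.shape)]
            ),
            births=np.zeros((2,) + grid.shape),
        )
        with pytest.warns(UserWarning, match="zero population"):
            result = population_weighted_exposure(np.ones(grid.shape), pop, "empty")
        assert np.isnan(result)

    def test_total_exposure_decomposes_over_subgroups(self, population, scenario_set):
        """The total-population exposure equals the population-share-weighted
        mean of subgroup exposures plus the multiracial-remainder term."""
        conc = scenario_set.baseline["NO2"].values
        total_w = population.counts[0].sum(axis=0)
        p_total = total_w.sum()
        acc = 0.0
        remainder = total_w.copy()
        for sub in population.subgroups[1:]:
            w = population.counts[population.subgroup_index(sub)].sum(axis=0)
            remainder -= w
            share = w.sum() / p_total
            if w.sum() > 0:
                acc += share * population_weighted_exposure(conc, population, sub)
        acc += (conc * remainder).sum() / p_total
        assert population_weighted_exposure(conc, population, "total") == pytest.approx(
            acc, rel=1e-10
        )


class TestRelativeDisparity:
    def test_subgroup_equal_to_national_is_one(self):
        df = relative_disparity({"black": 5.0}, national=5.0)
        assert df.iloc[0]["relative"] == 1.0
        assert not df.iloc[0]["above_national"]

    def test_double_national_is_two(self):
        df = relative_disparity({"black": 10.0}, national=5.0)
        assert df.iloc[0]["relative"] == 2.0
        assert df.iloc[0]["above_national"]

    def test_zero_national_rejected(self):
        with pytest.raises(ValueError, match="national value is zero"):
            relative_disparity({"black": 1.0}, national=0.0)

    def test_invariant_under_uniform_field_scaling(self, population, scenario_set):
        conc = scenario_set.baseline["PM2.5"].values
        for k in (0.5, 3.0):
            base = relative_disparity(
                {"black": population_weighted_exposure(conc, population, "black")},
                population_weighted_exposure(conc, population, "total"),
            )
            scaled = relative_disparity(
                {"black": population_weighted_exposure(k * conc, population, "black")},
                population_weighted_exposure(k * conc, population, "total"),
            )
            assert scaled.iloc[0]["relative"] == pytest.approx(
                base.iloc[0]["relative"], rel=1e-12
            )

    def test_invariant_under_uniform_population_scaling(self, population, scenario_set):
        conc = scenario_set.baseline["PM2.5"].values
        scaled_pop = PopulationGrid(
            grid=population.grid,
            age_bins=population.age_bins,
            subgroups=population.subgroups,
            counts=population.counts * 7.0,
            births=population.births * 7.0,
        )
        for sub in ("black", "hispanic"):
            a = population_weighted_exposure(conc, population, sub) / (
                population_weighted_exposure(conc, population, "total")
            )
            b = population_weighted_exposure(conc, scaled_pop, sub) / (
                population_weighted_exposure(conc, scaled_pop, "total")
            )
            assert a == pytest.approx(b, rel=1e-12)


def two_cell_world(hotspot=8.0, background=2.0, p_sub=100.0, p_other=900.0):
    """Closed-form two-cell setup: one subgroup lives entirely in the hotspot cell.

    relative exposure disparity of the subgroup =
        C_hot * (P_total) / (P_hot*C_hot + P_other*C_bg)
    """
    grid = GridDefinition.regular(1, 2, origin=(30.0, -100.0), resolution=(1.0, 1.0))
    conc = np.array([[hotspot, background]])
    counts = np.zeros((3, 1, 1, 2))
    counts[1, 0, 0, 0] = p_sub            # subgroup in hotspot cell only
    counts[2, 0, 0, 1] = p_other          # rest elsewhere
    counts[0] = counts[1] + counts[2]
    pop = PopulationGrid(
        grid=grid,
        age_bins=[(0.0, 100.0)],
        subgroups=["total", "colocated", "other"],
        counts=counts,
        births=np.zeros((3, 1, 2)),
    )
    total_pop = p_sub + p_other
    expected_rel = hotspot * total_pop / (p_sub * hotspot + p_other * background)
    return grid, conc, pop, expected_rel


class TestSubgroupBurden:
    def test_hotspot_colocated_subgroup_disparity_matches_closed_form(self):
        grid, conc, pop, expected = two_cell_world()
        national = population_weighted_exposure(conc, pop, "total")
        rel = population_weighted_exposure(conc, pop, "colocated") / national
        assert rel > 1.0
        assert rel == pytest.approx(expected, abs=1e-6)

    def test_uniform_shares_and_rates_give_unit_disparity(self, grid, counties, weights):
        """Identical rates and spatially uniform subgroup shares: every
        subgroup's burden rate equals the national rate."""
        rng = np.random.default_rng(2)
        conc_base = ConcentrationField("NO2", rng.uniform(3, 20, grid.shape), grid)
        conc_sens = ConcentrationField("NO2", conc_base.values * 0.6, grid)
        total = rng.uniform(100, 1000, grid.shape)
        counts = np.stack([total, 0.2 * total, 0.3 * total])[:, None]
        pop = PopulationGrid(
            grid=grid,
            age_bins=[(0.0, 100.0)],
            subgroups=["total", "a", "b"],
            counts=counts,
            births=np.zeros((3,) + grid.shape),
        )
        rows = []
        for c in counties.counties:
            for sub in ("total", "a", "b"):
                rows.append(
                    {
                        "level": "county",
                        "region_id": c.county_id,
                        "state_id": c.state_id,
                        "cause": "mortality",
                        "age_group": "age_standardized",
                        "subgroup": sub,
                        "rate": 700.0,
                        "suppressed": False,
                        "provenance": "county",
                    }
                )
        rates = RateTable(pd.DataFrame(rows))
        from airburden.risk import LogLinearRR

        model = LogLinearRR("x", 1.2, 1.1, 1.3, increment=10.0, counterfactual=2.0, units="ppb")
        kw = dict(
            baseline_field=conc_base,
            sensitivity_field=conc_sens,
            pop=pop,
            rates=rates,
            weights=weights,
            model=model,
            endpoint="x",
            cause="mortality",
        )
        national = subgroup_burden_rate(subgroup="total", rate_subgroup="total", **kw)
        for sub in ("a", "b"):
            rate = subgroup_burden_rate(subgroup=sub, **kw)
            assert rate / national == pytest.approx(1.0, rel=1e-9)

    def test_rate_scale_invariance_under_population_doubling(self, grid, counties, weights):
        rng = np.random.default_rng(5)
        conc_base = ConcentrationField("NO2", rng.uniform(3, 20, grid.shape), grid)
        conc_sens = ConcentrationField("NO2", conc_base.values * 0.5, grid)
        total = rng.uniform(100, 1000, grid.shape)
        counts = np.stack([total, 0.25 * total])[:, None]
        rows = [
            {
                "level": "county",
                "region_id": c.county_id,
                "state_id": c.state_id,
                "cause": "mortality",
                "age_group": "age_standardized",
                "subgroup": "a",
                "rate": 650.0,
                "suppressed": False,
                "provenance": "county",
            }
            for c in counties.counties
        ]
        rates = RateTable(pd.DataFrame(rows))
        from airburden.risk import LogLinearRR

        model = LogLinearRR("x", 1.2, 1.1, 1.3, increment=10.0, counterfactual=2.0, units="ppb")

        def rate_for(scale):
            pop = PopulationGrid(
                grid=grid,
                age_bins=[(0.0, 100.0)],
                subgroups=["total", "a"],
                counts=counts * scale,
                births=np.zeros((2,) + grid.shape),
            )
            return subgroup_burden_rate(
                baseline_field=conc_base,
                sensitivity_field=conc_sens,
                pop=pop,
                rates=rates,
                weights=weights,
                model=model,
                endpoint="x",
                cause="mortality",
                subgroup="a",
            )

        assert rate_for(2.0) == pytest.approx(rate_for(1.0), rel=1e-12)


class TestGapFillSensitivity:
    def _recompute_factory(self, weight_on_gap_filled):
        """Relative disparities as a direct linear function of two rates."""

        def recompute(rt):
            r_filled = float(
                rt.select(level="county", region_id="c0", subgroup="black")["rate"].iloc[0]
            )
            r_plain = float(
                rt.select(level="county", region_id="c1", subgroup="black")["rate"].iloc[0]
            )
            value = weight_on_gap_filled * r_filled + (1 - weight_on_gap_filled) * r_plain
            return {"black": value / 700.0, "white": 1.0}

        return recompute

    def _filled_table(self):
        rt = _rate_rows(
            [
                ("county", "c0", "s0", "black", None, True),
                ("county", "c1", "s0", "black", 700.0, False),
                ("state", "s0", "s0", "black", 700.0, False),
                ("national", "US", "US", "total", 700.0, False),
            ]
        )
        filled, _ = gap_fill(rt)
        return filled

    def test_zero_perturbation_changes_nothing(self):
        filled = self._filled_table()
        res = gap_fill_sensitivity(filled, 0.0, self._recompute_factory(0.5))
        assert (res.report["shift_up"] == 0).all()
        assert (res.report["shift_down"] == 0).all()
        assert all(res.ranking_unchanged.values())

    def test_no_gap_filled_entries_means_no_shift(self):
        rt = _rate_rows(
            [
                ("county", "c0", "s0", "black", 700.0, False),
                ("county", "c1", "s0", "black", 700.0, False),
                ("state", "s0", "s0", "black", 700.0, False),
                ("national", "US", "US", "total", 700.0, False),
            ]
        )
        res = gap_fill_sensitivity(rt, 0.2, self._recompute_factory(0.5))
        assert (res.report["shift_up"] == 0).all()

    def test_shift_matches_closed_form(self):
        """One county's rate is gap-filled with weight w in the disparity:
        scaling it by (1 + p) shifts the disparity by exactly w * p * r/700."""
        filled = self._filled_table()
        w = 0.6
        res = gap_fill_sensitivity(filled, 0.2, self._recompute_factory(w))
        row = res.report[res.report["subgroup"] == "black"].iloc[0]
        assert row["shift_up"] == pytest.approx(w * 0.2 * 700.0 / 700.0, rel=1e-12)
        assert row["shift_down"] == pytest.approx(-w * 0.2, rel=1e-12)

    def test_perturbation_at_or_above_one_rejected(self):
        filled = self._filled_table()
        with pytest.raises(ValueError, match="fraction below 1"):
            gap_fill_sensitivity(filled, 1.0, self._recompute_factory(0.5))

    def test_unfilled_table_rejected(self):
        rt = _rate_rows(
            [
                ("county", "c0", "s0", "black", None, True),
                ("national", "US", "US", "total", 700.0, False),
            ]
        )
        with pytest.raises(ValueError, match="gap-filled"):
            gap_fill_sensitivity(rt, 0.2, lambda r: {"black": 1.0})
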