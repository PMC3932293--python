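"""Budget-impact model: projection, shares, fracture counts, cost deltas."""

import dataclasses

import pytest

from osteohta import budget_impact as bi
from osteohta.parameters import TreatmentProfile, ValidationError
from osteohta.synthetic_inputs import (
    BaselineHazards,
    make_population_projection,
)


def _profile(name="x", rrr=0.0, compliance=1.0, cost=0.0):
    return TreatmentProfile(
        name=name, rrr_hip=rrr, rrr_vertebral=rrr, rrr_other=rrr,
        compliance=compliance, annual_drug_cost=cost,
    )


@pytest.fixture(scope="module")
def default_run(params):
    return bi.run_default_bim(params)


class TestTreatedPopulation:
    def test_zero_uptake_gives_zero_treated(self):
        proj = make_population_projection({"45+": 1_000_000}, 0.0)
        treated = bi.project_treated(proj, {y: 0.0 for y in proj.years()})
        assert all(v == 0.0 for v in treated.totals.values())

    def test_treated_counts_scale_linearly_with_population(self):
        small = make_population_projection({"45+": 1_000_000}, 0.0)
        large = make_population_projection({"45+": 2_000_000}, 0.0)
        rate = {y: 0.1 for y in small.years()}
        t_small = bi.project_treated(small, rate)
        t_large = bi.project_treated(large, rate)
        for y in t_small.years():
            assert t_large.totals[y] == pytest.approx(2 * t_small.totals[y])

    def test_uptake_anchors_reproduced_exactly(self, params, default_run):
        with_world = default_run["with_world"]
        assert with_world.by_product[2011]["denosumab"] == pytest.approx(60_000, abs=1e-6)
        assert with_world.by_product[2013]["denosumab"] == pytest.approx(150_000, abs=1e-6)

    def test_out_of_range_rate_rejected(self):
        proj = make_population_projection({"45+": 1_000_000}, 0.0)
        with pytest.raises(ValidationError):
            bi.project_treated(proj, {2010: 1.2})


class TestMarketShares:
    def test_with_scenario_final_year_share(self, params, default_run):
        with_world = default_run["with_world"]
        total = with_world.totals[2013]
        share = params.market_shares.share(2013, "denosumab")
        assert with_world.by_product[2013]["denosumab"] == pytest.approx(total * share)

    def test_pre_entry_year_identical_in_both_scenarios(self, default_run):
        w = default_run["with_world"].by_product[2010]
        wo = default_run["without_world"].by_product[2010]
        for product, n in w.items():
            assert wo.get(product, 0.0) == pytest.approx(n)

    def test_without_scenario_conserves_patients(self, default_run):
        for year in default_run["treated"].years():
            w = sum(default_run["with_world"].by_product[year].values())
            wo = sum(default_run["without_world"].by_product[year].values())
            assert w == pytest.approx(wo)
            assert default_run["without_world"].by_product[year].get("denosumab", 0.0) == 0.0

    def test_uniform_shares_split_evenly(self):
        from osteohta.parameters import MarketShareTable

        shares = MarketShareTable.from_raw({2011: {"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25}})
        treated = bi.TreatedPopulation(totals={2011: 1000.0})
        split = bi.apply_market_shares(treated, shares, "with")
        assert all(v == pytest.approx(250.0) for v in split.by_product[2011].values())

    def test_missing_scenario_year_raises(self, params):
        treated = bi.TreatedPopulation(totals={1999: 10.0})
        with pytest.raises(KeyError, match="1999"):
            bi.apply_market_shares(treated, params.market_shares, "with")


class TestExpectedFractures:
    def test_hand_arithmetic_single_product(self):
        # 1,000 patients x 0.01 annual hip risk x (1 - 0.40) = 6.0
        hz = BaselineHazards.flat({"hip": 0.01, "vertebral": 0.0, "other": 0.0})
        treated = bi.TreatedPopulation(
            totals={2011: 1000.0}, by_product={2011: {"x": 1000.0}}
        )
        counts = bi.expected_fractures(treated, {"x": _profile(rrr=0.4)}, hz)
        assert counts[2011]["hip"] == pytest.approx(6.0, rel=1e-12)

    def test_zero_efficacy_makes_scenarios_identical(self, params, default_run):
        profiles = {
            name: dataclasses.replace(p, rrr_hip=0.0, rrr_vertebral=0.0, rrr_other=0.0)
            for name, p in params.treatments.items()
        }
        hz = default_run["hazards"]
        w = bi.expected_fractures(default_run["with_world"], profiles, hz)
        wo = bi.expected_fractures(default_run["without_world"], profiles, hz)
        for year in w:
            for ftype in w[year]:
                assert w[year][ftype] == pytest.approx(wo[year][ftype])

    def test_calibrated_hazards_reproduce_base_year_counts(self, default_run):
        targets = default_run["calibration_targets"]
        base_year = min(default_run["with_outcome"].years())
        got = default_run["with_outcome"].fractures[base_year]
        for ftype, target in targets.items():
            assert got[ftype] == pytest.approx(target, rel=0.01)


class TestAvoidedAndImpact:
    def test_printed_scenario_subtraction(self, printed):
        rows = printed["scenario_fractures"]
        avoided = bi.fractures_avoided(
            {y: {"hip": rows["hip"]["with"][y], "vertebral": rows["vertebral"]["with"][y]}
             for y in rows["hip"]["with"]},
            {y: {"hip": rows["hip"]["without"][y], "vertebral": rows["vertebral"]["without"][y]}
             for y in rows["hip"]["without"]},
        )
        assert [avoided[y]["hip"] for y in (2011, 2012, 2013)] == [93, 163, 275]
        assert [avoided[y]["vertebral"] for y in (2011, 2012, 2013)] == [136, 225, 372]

    def test_identical_scenarios_avoid_nothing(self, default_run):
        same = bi.fractures_avoided(default_run["with_outcome"], default_run["with_outcome"])
        assert all(v == 0.0 for row in same.values() for v in row.values())

    def test_year_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bi.fractures_avoided({2011: {"hip": 1.0}}, {2012: {"hip": 1.0}})

    def test_budget_totals_from_printed_category_deltas(self, printed):
        impact = bi.BudgetImpact.from_category_deltas_keur(printed["budget_impact_keur"])
        keur = impact.in_thousands()
        assert keur[2011]["total"] == -5190
        assert keur[2012]["total"] == -8923
        assert keur[2013]["total"] == -14904

    def test_total_equals_sum_of_categories(self, default_run):
        impact = default_run["impact"]
        for year in impact.years():
            keur = impact.in_thousands()[year]
            assert abs(keur["total"] - sum(keur[c] for c in bi.COST_CATEGORIES)) <= 2

    def test_all_zero_deltas_give_zero_total(self):
        impact = bi.BudgetImpact(deltas={2011: {c: 0.0 for c in bi.COST_CATEGORIES}})
        assert impact.total(2011) == 0.0

    def test_inpatient_share_of_avoided_costs(self, printed):
        impact = bi.BudgetImpact.from_category_deltas_keur(printed["budget_impact_keur"])
        assert round(100 * bi.inpatient_share(impact, 2011), 1) == 82.4

    def test_scenario_symmetry_yields_zero_impact(self, params, default_run):
        # If denosumab is made identical to the single product it displaces,
        # both worlds coincide and every category delta vanishes.
        strontium = params.treatments["strontium_ranelate"]
        profiles = dict(params.treatments)
        profiles["denosumab"] = dataclasses.replace(strontium, name="denosumab")
        treated = default_run["treated"]
        hz = default_run["hazards"]
        with_world = bi.apply_market_shares(treated, params.market_shares, "with")
        without_world = bi.apply_market_shares(
            treated, params.market_shares, "without",
            displaced_weights={"strontium_ranelate": 1.0},
        )
        w = bi.scenario_outcome(with_world, profiles, hz, params.catalogue)
        wo = bi.scenario_outcome(without_world, profiles, hz, params.catalogue)
        impact = bi.compute_budget_impact(w, wo)
        for year in impact.years():
            for cat in bi.COST_CATEGORIES:
                assert impact.deltas[year][cat] == pytest.approx(0.0, abs=1e-6)

    def test_medications_impact_monotone_in_denosumab_price(self, params, default_run):
        deltas = []
        for price in (100.0, 400.0, 800.0):
            profiles = dict(params.treatments)
            profiles["denosumab"] = dataclasses.replace(
                profiles["denosumab"], annual_drug_cost=price
            )
            w = bi.scenario_outcome(
                default_run["with_world"], profiles, default_run["hazards"], params.catalogue
            )
            wo = bi.scenario_outcome(
                default_run["without_world"], profiles, default_run["hazards"], params.catalogue
            )
            deltas.append(bi.compute_budget_impact(w, wo).deltas[2013]["medications"])
        assert deltas[0] < deltas[1] < deltas[2]

    def test_avoided_counts_nonnegative_when_denosumab_dominates(self, default_run):
        # denosumab's compliance-weighted efficacy exceeds every displaced
        # product's, so the with-world can only avoid fractures
        for year, row in default_run["avoided"].items():
            for ftype, v in row.items():
                assert v >= -1e-9

    def test_poisson_sampling_mode_is_seeded(self, default_run):
        expected = default_run["with_outcome"].fractures
        a = bi.sample_fractures(expected, seed=3)
        b = bi.sample_fractures(expected, seed=3)
        assert a == b
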