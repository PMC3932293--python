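"""Markov cohort engine: transitions, accumulation, ICERs, PSA, CEAC."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteohta import markov_cea as mc
from osteohta.parameters import DiscountSpec, TreatmentProfile
from conftest import flat_hazards, flat_life_table

_H, _HIP, _PH1, _PH, _VERT, _PV1, _PV, _OTH, _DEAD = range(9)


def profile(rrr_hip=0.0, rrr_vertebral=0.0, rrr_other=0.0, compliance=1.0,
            cost=0.0, duration=5.0, offset=1.0, name="test"):
    return TreatmentProfile(
        name=name, rrr_hip=rrr_hip, rrr_vertebral=rrr_vertebral,
        rrr_other=rrr_other, compliance=compliance, annual_drug_cost=cost,
        treatment_duration=duration, offset_time=offset,
    )


class TestTransitionMatrix:
    def test_degenerate_inputs_give_pure_tunnel_flow(self, zero_mortality):
        m = mc.build_transition_matrix(
            65.0, profile(), flat_hazards(), zero_mortality
        ).array
        assert m[_H, _H] == 1.0
        assert m[_HIP, _PH1] == 1.0  # hip event flows to the post-hip tunnel
        assert m[_VERT, _PV1] == 1.0
        assert m[_OTH, _H] == 1.0  # other fractures recover to healthy
        assert m[_DEAD, _DEAD] == 1.0

    def test_treatment_scales_hip_entry_probability(self, zero_mortality):
        # hand arithmetic: 0.010 x (1 - 0.40) with full efficacy weight
        m = mc.build_transition_matrix(
            65.0, profile(rrr_hip=0.40), flat_hazards(hip=0.010), zero_mortality
        ).array
        assert m[_H, _HIP] == pytest.approx(0.006, abs=1e-15)

    def test_post_states_permit_refracture_and_death(self):
        m = mc.build_transition_matrix(
            65.0, profile(), flat_hazards(hip=0.02, vertebral=0.01, other=0.01, excess=2.0),
            flat_life_table(0.05),
        ).array
        for row in (_PH1, _PH, _PV1, _PV):
            assert m[row, _HIP] > 0 and m[row, _VERT] > 0 and m[row, _OTH] > 0
        # death reachable from every living state
        assert np.all(m[:_DEAD, _DEAD] > 0)
        # first post-hip year carries the mortality multiplier
        assert m[_PH1, _DEAD] == pytest.approx(2 * 0.05)
        assert m[_PH, _DEAD] == pytest.approx(0.05)

    @given(
        hip=st.floats(0.0, 0.3), vert=st.floats(0.0, 0.3),
        other=st.floats(0.0, 0.3), q=st.floats(0.0, 1.0),
        excess=st.floats(1.0, 5.0), rrr=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_rows_always_stochastic(self, hip, vert, other, q, excess, rrr):
        m = mc.build_transition_matrix(
            70.0, profile(rrr_hip=rrr, rrr_vertebral=rrr, rrr_other=rrr),
            flat_hazards(hip=hip, vertebral=vert, other=other, excess=excess),
            flat_life_table(q),
        ).array
        assert np.all(m >= 0) and np.all(m <= 1)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_unstochastic_row_is_rejected_not_renormalized(self, zero_mortality):
        with pytest.raises(mc.ConstructionError):
            mc.build_transition_matrix(
                65.0, profile(),
                flat_hazards(hip=0.5, vertebral=0.4, other=0.3), zero_mortality,
            )


class TestCohortEngine:
    def test_two_cycle_hand_example_matches_matrix_power(self, zero_mortality):
        hz = flat_hazards(hip=0.1)
        traj = mc.run_cohort(65.0, profile(), hz, zero_mortality, max_age=66.0)
        occ = traj.occupancy  # public 7-state view
        assert occ[1][0] == pytest.approx(0.9)   # healthy
        assert occ[1][1] == pytest.approx(0.1)   # hip event
        assert occ[2][1] == pytest.approx(0.09)  # new hip fractures
        assert occ[2][2] == pytest.approx(0.1)   # six months after hip
        m = mc.build_transition_matrix(65.0, profile(), hz, zero_mortality).array
        v0 = np.zeros(9); v0[_H] = 1.0
        assert np.allclose(traj.occupancy_internal[2], v0 @ np.linalg.matrix_power(m, 2), atol=1e-15)

    @pytest.mark.parametrize("n_cycles", [1, 5, 10])
    def test_engine_equals_matrix_power_for_age_constant_inputs(self, n_cycles):
        hz = flat_hazards(hip=0.02, vertebral=0.03, other=0.01, excess=2.0)
        lt = flat_life_table(0.01)
        p = profile(rrr_hip=0.4, rrr_vertebral=0.68, rrr_other=0.2, duration=100.0)
        traj = mc.run_cohort(65.0, p, hz, lt, max_age=65.0 + 0.5 * n_cycles)
        m = mc.build_transition_matrix(65.0, p, hz, lt, on_treatment=True).array
        v0 = np.zeros(9); v0[_H] = 1.0
        expected = v0 @ np.linalg.matrix_power(m, n_cycles)
        assert np.allclose(traj.occupancy_internal[n_cycles], expected, atol=1e-12)

    def test_conservation_and_monotone_mortality_over_lifetime(self, params):
        hazards, life, start, stop = mc.cohort_background_from_config(params.config)
        traj = mc.run_cohort(start, params.treatments["denosumab"], hazards, life, max_age=stop)
        sums = traj.occupancy.sum(axis=1)
        assert np.all(np.abs(sums - 1.0) <= 1e-12)
        dead = traj.dead_fraction
        assert np.all(np.diff(dead) >= -1e-15)
        assert dead[-1] > 0.999  # lifetime horizon empties the cohort

    def test_all_dead_start_is_constant(self, zero_mortality):
        v0 = [0, 0, 0, 0, 0, 0, 1.0]
        traj = mc.run_cohort(65.0, profile(), flat_hazards(hip=0.1), zero_mortality,
                             max_age=70.0, initial=v0)
        assert np.all(traj.occupancy[:, -1] == 1.0)

    def test_immortal_healthy_cohort_truncates_at_max_age(self, zero_mortality):
        # horizon short of the terminal closure row, where death is forced to 1
        traj = mc.run_cohort(65.0, profile(), flat_hazards(), zero_mortality, max_age=105.0)
        assert traj.n_cycles == 80
        assert np.all(traj.occupancy[:, 0] == 1.0)


class TestAccumulation:
    def test_discounting_closed_form_at_one_year(self):
        assert DiscountSpec(0.03).factor(1.0) * 100 == pytest.approx(97.0874, abs=1e-4)

    def test_ten_healthy_years_undiscounted(self, params, zero_mortality):
        cat = dataclasses.replace(params.catalogue, utility_healthy=1.0)
        traj = mc.run_cohort(65.0, profile(), flat_hazards(), zero_mortality, max_age=75.0)
        res = mc.accumulate_outcomes(traj, cat, profile(), DiscountSpec(0.0))
        assert res.total_qalys == pytest.approx(10.0)
        assert res.total_cost == 0.0

    def test_single_vertebral_cycle_costs_and_utility(self, params):
        # one cohort member spends one cycle in the vertebral event state
        traj = mc.CohortTrajectory(
            start_age=65.0, cycle_length=0.5,
            arms={"compliant": np.array([
                [0, 0, 0, 0, 1.0, 0, 0, 0, 0],
                [0, 0, 0, 0, 0, 1.0, 0, 0, 0],
            ])},
            weights={"compliant": 1.0},
            on_drug={"compliant": np.array([False])},
        )
        res = mc.accumulate_outcomes(traj, params.catalogue, profile(), DiscountSpec(0.0))
        assert res.total_cost == pytest.approx(2476.0)
        assert res.total_qalys == pytest.approx(0.590 * 0.5)

    def test_zero_discount_reproduces_undiscounted_sums(self, params):
        hazards, life, start, stop = mc.cohort_background_from_config(params.config)
        p = params.treatments["risedronate"]
        traj = mc.run_cohort(start, p, hazards, life, max_age=stop)
        r0 = mc.accumulate_outcomes(traj, params.catalogue, p, DiscountSpec(0.0))
        u = mc._utility_vector(params.catalogue)
        occ = traj.occupancy_internal
        manual_q = float((occ[:-1] @ u).sum() * 0.5)
        assert r0.total_qalys == pytest.approx(manual_q, rel=1e-12)

    def test_drug_cost_follows_compliance_split(self, zero_mortality):
        # compliant arm pays 5 years, noncompliant arm pays 6 months
        p = profile(compliance=0.8, cost=100.0, duration=5.0, offset=0.0)
        traj = mc.run_cohort(65.0, p, flat_hazards(), zero_mortality, max_age=75.0)
        cat = mc.CostUtilityCatalogue(
            unit_cost_by_fracture={"hip": 0, "vertebral": 0, "other": 0},
            utility_first_year={"hip": 0.7, "vertebral": 0.59, "other": 0.9},
            utility_subsequent={"hip": 0.8, "vertebral": 0.93, "other": 1.0},
            utility_healthy=1.0,
        )
        res = mc.accumulate_outcomes(traj, cat, p, DiscountSpec(0.0))
        assert res.total_cost == pytest.approx(0.8 * 100 * 5 + 0.2 * 100 * 0.5)

    def test_qaly_monotonicity_in_efficacy(self, params):
        hazards, life, start, stop = mc.cohort_background_from_config(params.config)
        base = profile(rrr_hip=0.2, rrr_vertebral=0.2, rrr_other=0.2, duration=5.0)
        qalys, frac_costs = [], []
        for rrr in (0.0, 0.2, 0.5, 0.9):
            p = dataclasses.replace(base, rrr_hip=rrr)
            res = mc.run_strategy(p, hazards, life, params.catalogue,
                                  DiscountSpec(0.03), start_age=start, max_age=stop)
            qalys.append(res.total_qalys)
            frac_costs.append(res.total_cost)  # no drug cost: fracture costs only
        assert all(b >= a for a, b in zip(qalys, qalys[1:]))
        assert all(b <= a for a, b in zip(frac_costs, frac_costs[1:]))


class TestIcer:
    def _res(self, cost, q, name="x"):
        return mc.EconomicResult(strategy=name, total_cost=cost, total_qalys=q)

    def test_division_on_published_incremental_cells(self):
        # rounded difference from the published table; the printed ICER uses
        # unrounded internals, so only the division itself is asserted
        inc = mc.compute_icer(self._res(22399, 10.46, "d"), self._res(21621, 10.41, "a"))
        assert inc.delta_cost == pytest.approx(778)
        assert inc.icer == pytest.approx(778 / (10.46 - 10.41), rel=1e-9)
        inc2 = mc.compute_icer(self._res(22399, 10.46, "d"), self._res(22394, 10.39, "s"))
        assert inc2.delta_cost == pytest.approx(5)
        assert inc2.icer == pytest.approx(5 / 0.07, rel=1e-6)

    def test_dominance_flags(self):
        assert mc.compute_icer(self._res(99, 1.01), self._res(100, 1.0)).dominance == "dominant"
        assert mc.compute_icer(self._res(101, 0.99), self._res(100, 1.0)).dominance == "dominated"
        assert mc.compute_icer(self._res(100, 1.0), self._res(100, 1.0)).dominance is None

    def test_zero_qaly_difference_flags_infinite_icer(self):
        inc = mc.compute_icer(self._res(105, 1.0), self._res(100, 1.0))
        assert np.isinf(inc.icer) and inc.icer > 0

    def test_identical_zero_efficacy_strategies_have_zero_deltas(self, params):
        hazards, life, start, stop = mc.cohort_background_from_config(params.config)
        a = profile(cost=100.0, name="a")
        b = profile(cost=100.0, name="b")
        ra = mc.run_strategy(a, hazards, life, params.catalogue, DiscountSpec(0.03),
                             start_age=start, max_age=stop)
        rb = mc.run_strategy(b, hazards, life, params.catalogue, DiscountSpec(0.03),
                             start_age=start, max_age=stop)
        inc = mc.compute_icer(ra, rb)
        assert inc.delta_cost == 0.0 and inc.delta_qalys == 0.0


class TestPsa:
    def _spec(self, params, dists, strategies=None):
        hazards, life, start, stop = mc.cohort_background_from_config(params.config)
        strategies = strategies or {
            "denosumab": params.treatments["denosumab"],
            "strontium_ranelate": params.treatments["strontium_ranelate"],
        }
        return mc.PsaSpec(
            strategies=strategies, catalogue=params.catalogue, hazards=hazards,
            life_table=life, discount=params.discount, start_age=start,
            max_age=stop, distributions=dists,
        )

    def test_point_mass_psa_equals_deterministic_run(self, params):
        cat = params.catalogue
        dists = {
            "cost.hip": mc.PointMass(cat.unit_cost_by_fracture["hip"]),
            "utility.hip.first_year": mc.PointMass(cat.utility_first_year["hip"]),
            "compliance.denosumab": mc.PointMass(params.treatments["denosumab"].compliance),
            "hazard_scale.hip": mc.PointMass(1.0),
        }
        spec = self._spec(params, dists)
        draws = mc.run_psa(spec, 1, seed=7)
        det = mc.run_strategy(
            params.treatments["denosumab"], spec.hazards, spec.life_table,
            cat, params.discount, start_age=spec.start_age, max_age=spec.max_age,
        )
        j = draws.column("denosumab")
        assert draws.costs[0, j] == det.total_cost
        assert draws.qalys[0, j] == det.total_qalys

    def test_fixed_seed_reproduces_draws(self, params):
        dists = {"cost.hip": mc.Gamma.from_moments(8206.0, 1000.0)}
        spec = self._spec(params, dists)
        a = mc.run_psa(spec, 5, seed=11)
        b = mc.run_psa(spec, 5, seed=11)
        assert np.array_equal(a.costs, b.costs) and np.array_equal(a.qalys, b.qalys)

    def test_beta_moment_matching(self):
        # moment-matching oracle: empirical mean of 1e4 draws within 3 sd
        rng = np.random.default_rng(0)
        dist = mc.Beta.from_moments(0.7, 0.05)
        draws = np.array([dist.sample(rng) for _ in range(10_000)])
        assert abs(draws.mean() - 0.7) < 3 * 0.05 / np.sqrt(10_000)
        assert abs(draws.std() - 0.05) < 0.005

    def test_out_of_domain_draws_rejected_and_counted(self, params):
        # a utility distribution straddling 1 forces rejections
        dists = {"utility.hip.first_year": mc.Uniform(0.9, 1.5)}
        spec = self._spec(params, dists)
        draws = mc.run_psa(spec, 3, seed=5)
        assert draws.n_rejected > 0
        assert draws.costs.shape == (3, 2)


class TestCeac:
    def _draws(self):
        # hand-built draws: intervention gains QALYs at varying cost
        costs = np.array([[100.0, 0.0], [50.0, 0.0], [-10.0, 0.0], [200.0, 0.0]])
        qalys = np.array([[1.01, 1.0], [1.02, 1.0], [1.005, 1.0], [1.001, 1.0]])
        return mc.PsaDraws(strategies=("denosumab", "comp"), costs=costs,
                           qalys=qalys, seed=0)

    def test_probability_matches_direct_counting(self):
        draws = self._draws()
        for threshold in (0, 1000, 5000, 100_000, 500_000):
            nmb = threshold * (draws.qalys[:, 0] - draws.qalys[:, 1]) - (
                draws.costs[:, 0] - draws.costs[:, 1]
            )
            expected = float(np.mean(nmb > 0))
            assert mc.probability_cost_effective(draws, threshold, "comp") == expected

    def test_all_dominant_draws_are_certain_at_any_threshold(self):
        draws = mc.PsaDraws(
            strategies=("denosumab", "comp"),
            costs=np.array([[90.0, 100.0]] * 3),
            qalys=np.array([[1.1, 1.0]] * 3),
            seed=0,
        )
        for t in (0, 1, 30_000):
            assert mc.probability_cost_effective(draws, t, "comp") == 1.0

    def test_zero_threshold_with_pure_cost_increase_is_zero(self):
        draws = mc.PsaDraws(
            strategies=("denosumab", "comp"),
            costs=np.array([[110.0, 100.0]] * 3),
            qalys=np.array([[1.1, 1.0]] * 3),
            seed=0,
        )
        assert mc.probability_cost_effective(draws, 0.0, "comp") == 0.0

    def test_ceac_monotone_in_threshold_for_qaly_gaining_intervention(self):
        curve = mc.ceac(self._draws(), np.linspace(0, 300_000, 31), "comp")
        assert (np.diff(curve["probability"]) >= 0).all()

    def test_ties_count_as_not_cost_effective(self):
        draws = mc.PsaDraws(
            strategies=("denosumab", "comp"),
            costs=np.array([[100.0, 100.0]]),
            qalys=np.array([[1.0, 1.0]]),
            seed=0,
        )
        assert mc.probability_cost_effective(draws, 30_000, "comp") == 0.0


class TestCalibrationDemo:
    def test_qualitative_ordering_attainable_under_documented_background(self, params):
        demo = mc.run_calibration_demo(params)
        strontium = demo["icers"]["strontium_ranelate"]
        assert strontium.delta_qalys > 0
        assert 0 < strontium.icer < 1000
        for inc in demo["icers"].values():
            assert inc.delta_qalys > 0
            assert inc.dominance != "dominated"
            assert inc.icer < 30_000  # cost-effective at the stated threshold
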