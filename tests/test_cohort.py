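import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lpi_cea import (
    LPI,
    OBSERVATION,
    ScenarioConfig,
    build_state_space,
    cycle_rewards,
    run_cohort,
    transition_matrix,
)
from lpi_cea.parameters import SocietalInputs

from .conftest import annuity_due


class TestStateSpace:
    def test_lpi_arm_has_no_crisis_state(self):
        space = build_state_space(LPI)
        assert space.n == 7
        assert "AACC" not in space
        assert "PACS_LPIOPEN" not in space

    def test_observation_arm_has_crisis_pathway(self):
        space = build_state_space(OBSERVATION)
        assert space.n == 9
        assert "AACC" in space and "PACS_LPIOPEN" in space

    def test_unknown_arm(self):
        with pytest.raises(ValueError):
            build_state_space("placebo")


class TestTransitionMatrix:
    def test_rows_are_stochastic(self, params):
        for arm in (LPI, OBSERVATION):
            T = transition_matrix(params, arm, 45)
            assert np.all(T >= 0) and np.all(T <= 1)
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_pacs_row_lpi(self, params):
        space = build_state_space(LPI)
        T = transition_matrix(params, LPI, 45)
        row = T[space.index("PACS")]
        assert row[space.index("PAC_y1")] == pytest.approx(0.0117)
        assert row[space.index("PACS")] == pytest.approx(0.9883)

    def test_pacs_stay_probability_observation(self, params):
        space = build_state_space(OBSERVATION)
        T = transition_matrix(params, OBSERVATION, 45)
        stay = T[space.index("PACS"), space.index("PACS")]
        assert stay == pytest.approx(1 - 0.0218 - 0.00097)

    def test_zeroed_probabilities_stop_all_progression(self, zeroed_params):
        """With every clinical transition at zero, the only remaining moves
        are the tunnel exits (first-year states drain into their established
        twins); every established state is absorbing."""
        for arm in (LPI, OBSERVATION):
            space = build_state_space(arm)
            T = transition_matrix(zeroed_params, arm, 45)
            assert T[space.index("PACS_y1"), space.index("PACS")] == 1.0
            assert T[space.index("PAC_y1"), space.index("PAC")] == 1.0
            established = [i for i, s in enumerate(space.states)
                           if not s.endswith("_y1")]
            sub = T[np.ix_(established, established)]
            np.testing.assert_array_equal(sub, np.eye(len(established)))

    def test_biblind_is_absorbing(self, params):
        for arm in (LPI, OBSERVATION):
            space = build_state_space(arm)
            row = transition_matrix(params, arm, 45)[space.index("BIBLIND")]
            assert row[space.index("BIBLIND")] == 1.0
            assert row.sum() == 1.0

    def test_crisis_resolves_to_open_angle_state(self, params):
        space = build_state_space(OBSERVATION)
        T = transition_matrix(params, OBSERVATION, 45)
        assert T[space.index("AACC"), space.index("PACS_LPIOPEN")] == 1.0
        # post-crisis patients progress at the iridotomy-arm rate
        assert T[space.index("PACS_LPIOPEN"),
                 space.index("PAC_y1")] == pytest.approx(0.0117)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        p_pac=st.floats(0, 0.5), p_pacg=st.floats(0, 1),
        p_uni=st.floats(0, 1), p_bi=st.floats(0, 1), p_aacc=st.floats(0, 0.5),
    )
    def test_row_stochastic_for_any_valid_probabilities(
            self, p_pac, p_pacg, p_uni, p_bi, p_aacc):
        from lpi_cea import default_parameters

        trial = default_parameters().replace(
            p_pacs_pac_obs=p_pac, p_pac_pacg_obs=p_pacg,
            p_pacg_uniblind=p_uni, p_uni_biblind=p_bi, p_pacs_aacc_obs=p_aacc)
        T = transition_matrix(trial, OBSERVATION, 45)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(T >= 0)


class TestCycleRewards:
    def test_first_year_costs_differ_by_arm(self, params):
        assert cycle_rewards(params, LPI, "PACS_y1", 0, 40) == (98_393, 1.0)
        assert cycle_rewards(params, OBSERVATION, "PACS_y1", 0, 40) == (
            19_560, 1.0)

    def test_pacg_reward_includes_expected_trabeculectomy(self, params):
        cost, util = cycle_rewards(params, OBSERVATION, "PACG", 3, 45)
        assert cost == pytest.approx(48_545 + 0.0088 * 697_008)
        assert util == pytest.approx(0.75 - 0.0088 * 0.01)

    def test_crisis_year_reward(self, params):
        assert cycle_rewards(params, OBSERVATION, "AACC", 2, 42) == (
            107_167, 0.99)

    def test_post_crisis_follow_up_uses_iridotomy_cost(self, params):
        cost, util = cycle_rewards(params, OBSERVATION, "PACS_LPIOPEN", 5, 45)
        assert (cost, util) == (23_780, 1.0)

    def test_unknown_state_rejected(self, params):
        with pytest.raises(ValueError):
            cycle_rewards(params, LPI, "AACC", 0, 40)

    def test_societal_block_adds_travel_and_indirect_costs(self, params):
        societal = SocietalInputs(
            indirect_cost_biblind=1_000_000,
            visits_per_state={"PACS": 4, "BIBLIND": 2},
        )
        cost, _ = cycle_rewards(params, LPI, "PACS", 1, 41, societal=societal)
        assert cost == pytest.approx(23_780 + 4 * 4547)
        cost, _ = cycle_rewards(params, LPI, "BIBLIND", 1, 41,
                                societal=societal)
        assert cost == pytest.approx(44_745 + 2 * 4547 + 1_000_000)
        cost, _ = cycle_rewards(params, LPI, "UNIBLIND", 1, 41,
                                societal=societal)
        assert cost == pytest.approx(46_645 + 0.30 * 1_000_000)


class TestRunCohort:
    def test_all_healthy_qalys_equal_annuity_due(self, zeroed_params):
        res = run_cohort(zeroed_params, LPI, ScenarioConfig(40, 59))
        assert res.total_qaly == pytest.approx(annuity_due(0.02, 20),
                                               abs=1e-12)
        assert round(res.total_qaly, 4) == 16.6785

    def test_single_cycle_is_undiscounted(self, params):
        res = run_cohort(params, LPI, ScenarioConfig(40, 40))
        assert res.total_cost == pytest.approx(98_393)
        assert res.total_qaly == pytest.approx(1.0)

    def test_zero_discount_equates_totals(self, params):
        ps = params.replace(discount_rate=0.0)
        for arm in (LPI, OBSERVATION):
            res = run_cohort(ps, arm, ScenarioConfig(40, 59))
            assert res.total_cost == pytest.approx(res.undiscounted_cost)
            assert res.total_qaly == pytest.approx(res.undiscounted_qaly)

    def test_discounted_below_undiscounted(self, params, base_scenario):
        res = run_cohort(params, OBSERVATION, base_scenario)
        assert res.total_cost < res.undiscounted_cost
        assert res.total_qaly < res.undiscounted_qaly
        assert res.total_qaly <= base_scenario.horizon

    def test_trace_invariants(self, params, base_scenario):
        for arm in (LPI, OBSERVATION):
            trace = run_cohort(params, arm, base_scenario).trace
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0,
                                       atol=1e-12)
            assert np.all(trace.occupancy >= 0)
            assert np.all(trace.occupancy <= 1)
            biblind = trace.occupancy_of("BIBLIND")
            assert np.all(np.diff(biblind) >= -1e-15)

    def test_faster_progression_lowers_qalys(self, params, base_scenario):
        ref = run_cohort(params, OBSERVATION, base_scenario).total_qaly
        for name in ("p_pacs_pac_obs", "p_pac_pacg_obs", "p_pacg_uniblind",
                     "p_uni_biblind", "p_pacs_aacc_obs"):
            bumped = params.replace(**{name: getattr(params, name) * 2})
            assert run_cohort(bumped, OBSERVATION,
                              base_scenario).total_qaly <= ref

    def test_higher_cost_raises_total_cost(self, params, base_scenario):
        ref = run_cohort(params, OBSERVATION, base_scenario).total_cost
        for name in ("c_pacs_obs_follow", "c_pac_y1", "c_trab", "c_aacc"):
            bumped = params.replace(**{name: getattr(params, name) * 1.5})
            assert run_cohort(bumped, OBSERVATION,
                              base_scenario).total_cost >= ref

    def test_prophylaxis_weakly_dominates_on_effectiveness(
            self, params, base_scenario):
        lpi = run_cohort(params, LPI, base_scenario)
        obs = run_cohort(params, OBSERVATION, base_scenario)
        assert lpi.total_qaly >= obs.total_qaly

    def test_societal_requires_inputs(self, params):
        with pytest.raises(ValueError, match="societal"):
            run_cohort(params, LPI,
                       ScenarioConfig(40, 59, perspective="societal"))

    def test_trace_frame_layout(self, params, base_scenario):
        df = run_cohort(params, OBSERVATION, base_scenario).trace.to_frame()
        assert list(df["cycle"]) == list(range(20))
        assert df["age"].iloc[-1] == 59
        assert {"AACC", "PACS_LPIOPEN", "discounted_cost",
                "discounted_qaly"} <= set(df.columns)
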