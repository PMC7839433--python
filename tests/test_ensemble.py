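import numpy as np
import pandas as pd
import pytest

from ubn import (
    Cpt,
    Evidence,
    InputError,
    ModelSet,
    NodeSpec,
    Query,
    WeightError,
    average_query,
    build_network,
    eliminate_query,
    forward_sample,
    generate_fixture,
    likelihood_weights,
    robust_scan,
    scenario_query,
)
from conftest import random_model


def one_node_model(p: float, name: str = "X") -> "object":
    return build_network(
        [NodeSpec(name, ("x1", "x2"))], [Cpt(name, {(): (p, 1 - p)})]
    )


class TestAverageQuery:
    def test_degenerate_weights_select_one_member(self):
        ms = ModelSet(
            members=(("m1", one_node_model(0.2)), ("m2", one_node_model(0.6))),
            weights=(1.0, 0.0),
        )
        assert average_query(ms, Query("X", ("x1",))) == pytest.approx(0.2)

    def test_uniform_weights_give_arithmetic_mean(self):
        ms = ModelSet(
            members=(("m1", one_node_model(0.2)), ("m2", one_node_model(0.6))),
            weights=(0.5, 0.5),
        )
        assert average_query(ms, Query("X", ("x1",))) == pytest.approx(0.4)

    def test_matches_direct_weighted_sum_on_seeded_members(self):
        members = tuple(
            (f"m{i}", random_model(300 + i, n_nodes=3, max_states=2))
            for i in range(3)
        )
        w = (0.5, 0.3, 0.2)
        ms = ModelSet(members=members, weights=w)
        q = Query("N2", ("s0",))
        expected = sum(
            wi * eliminate_query(m, q) for wi, (_, m) in zip(w, members)
        )
        assert average_query(ms, q) == pytest.approx(expected, abs=1e-12)

    def test_missing_weights_directs_to_alternatives(self):
        ms = ModelSet(members=(("m1", one_node_model(0.2)),))
        with pytest.raises(WeightError, match="scenario_query|likelihood_weights"):
            average_query(ms, Query("X", ("x1",)))

    def test_uniform_average_equals_mean_of_scenarios(self):
        members = tuple(
            (f"m{i}", random_model(400 + i, n_nodes=3, max_states=2))
            for i in range(4)
        )
        ms = ModelSet(members=members, weights=(0.25,) * 4)
        q = Query("N2", ("s0",))
        sc = scenario_query(ModelSet(members=members), q)
        assert average_query(ms, q) == pytest.approx(
            np.mean(list(sc.results.values())), abs=1e-12
        )

    def test_scenario_range_contains_weighted_average(self):
        members = tuple(
            (f"m{i}", random_model(500 + i, n_nodes=3, max_states=2))
            for i in range(3)
        )
        q = Query("N2", ("s0",))
        lo, hi = scenario_query(ModelSet(members=members), q).range
        for w in ((0.1, 0.2, 0.7), (1 / 3,) * 3, (0.8, 0.1, 0.1)):
            avg = average_query(ModelSet(members=members, weights=w), q)
            assert lo - 1e-12 <= avg <= hi + 1e-12

    def test_evidence_node_absent_from_member_is_error(self):
        m1 = one_node_model(0.2)
        a = NodeSpec("A", ("a1", "a2"))
        x = NodeSpec("X", ("x1", "x2"), parents=("A",))
        m2 = build_network(
            [a, x],
            [
                Cpt("A", {(): (0.5, 0.5)}),
                Cpt("X", {("a1",): (0.3, 0.7), ("a2",): (0.9, 0.1)}),
            ],
        )
        ms = ModelSet(members=(("m1", m1), ("m2", m2)), weights=(0.5, 0.5))
        q = Query("X", ("x1",), (Evidence.hard("A", "a1"),))
        with pytest.raises(InputError, match="absent"):
            average_query(ms, q)


class TestLikelihoodWeights:
    def test_identical_members_get_uniform_weights(self):
        m = one_node_model(0.3)
        ms = ModelSet(members=(("a", m), ("b", m), ("c", m)))
        cases = pd.DataFrame({"X": ["x1", "x2", "x1"]})
        w = likelihood_weights(ms, cases)
        assert w == pytest.approx((1 / 3,) * 3, abs=1e-12)

    def test_single_case_bayes_closed_form(self):
        """P(x1)=0.9 vs 0.1, observed x1, uniform prior -> weights (0.9, 0.1)."""
        ms = ModelSet(members=(("m1", one_node_model(0.9)),
                               ("m2", one_node_model(0.1))))
        w = likelihood_weights(ms, pd.DataFrame({"X": ["x1"]}))
        assert w == pytest.approx((0.9, 0.1), abs=1e-12)

    def test_prior_weights_enter_multiplicatively(self):
        ms = ModelSet(members=(("m1", one_node_model(0.9)),
                               ("m2", one_node_model(0.1))))
        w = likelihood_weights(ms, pd.DataFrame({"X": ["x1"]}),
                               prior_weights=(0.1, 0.9))
        z = 0.1 * 0.9 + 0.9 * 0.1
        assert w == pytest.approx((0.09 / z, 0.09 / z), abs=1e-12)

    def test_weights_concentrate_on_generating_member(self):
        """Cases sampled from member A push its weight above 0.95."""
        m_a = random_model(600, n_nodes=3, max_states=2, density=0.8)
        m_b = random_model(601, n_nodes=3, max_states=2, density=0.8)
        cases = forward_sample(m_a, 500, rng=1)
        ms = ModelSet(members=(("A", m_a), ("B", m_b)))
        w = likelihood_weights(ms, cases)
        assert w[0] > 0.95

    def test_marginalizes_over_private_nodes(self):
        """A member with an extra hidden node is scored on the shared
        observable subset only."""
        m_small = one_node_model(0.37)
        h = NodeSpec("H", ("h1", "h2"))
        x = NodeSpec("X", ("x1", "x2"), parents=("H",))
        m_big = build_network(
            [h, x],
            [
                Cpt("H", {(): (0.5, 0.5)}),
                Cpt("X", {("h1",): (0.2, 0.8), ("h2",): (0.54, 0.46)}),
            ],
        )  # marginal P(x1) = 0.37 as well
        ms = ModelSet(members=(("small", m_small), ("big", m_big)))
        cases = pd.DataFrame({"X": ["x1", "x2", "x1", "x2"]})
        w = likelihood_weights(ms, cases)
        assert w == pytest.approx((0.5, 0.5), abs=1e-9)

    def test_zero_probability_member_gets_zero_weight_with_warning(self):
        m_zero = build_network(
            [NodeSpec("X", ("x1", "x2"))], [Cpt("X", {(): (0.0, 1.0)})]
        )
        ms = ModelSet(members=(("dead", m_zero), ("live", one_node_model(0.5))))
        with pytest.warns(UserWarning, match="zero probability"):
            w = likelihood_weights(ms, pd.DataFrame({"X": ["x1"]}))
        assert w == pytest.approx((0.0, 1.0))

    def test_all_members_zero_is_error(self):
        m_zero = build_network(
            [NodeSpec("X", ("x1", "x2"))], [Cpt("X", {(): (0.0, 1.0)})]
        )
        ms = ModelSet(members=(("a", m_zero), ("b", m_zero)))
        with pytest.raises(WeightError):
            with pytest.warns(UserWarning):
                likelihood_weights(ms, pd.DataFrame({"X": ["x1"]}))


class TestScenarioQuery:
    def test_singleton_set(self):
        ms = ModelSet(members=(("only", one_node_model(0.42)),))
        res = scenario_query(ms, Query("X", ("x1",)))
        assert res.results == {"only": pytest.approx(0.42)}
        assert res.range == (pytest.approx(0.42), pytest.approx(0.42))

    def test_range_is_extrema_of_members(self):
        ms = ModelSet(
            members=(
                ("m1", one_node_model(0.1)),
                ("m2", one_node_model(0.3)),
                ("m3", one_node_model(0.2)),
            )
        )
        res = scenario_query(ms, Query("X", ("x1",)))
        assert res.range == (pytest.approx(0.1), pytest.approx(0.3))

    def test_results_match_individual_queries(self):
        members = tuple(
            (f"m{i}", random_model(700 + i, n_nodes=3, max_states=2))
            for i in range(3)
        )
        q = Query("N1", ("s0",))
        res = scenario_query(ModelSet(members=members), q)
        for label, m in members:
            assert res.results[label] == pytest.approx(
                eliminate_query(m, q), abs=1e-15
            )


class TestRobustScan:
    def _two_scenario_set(self):
        # decision node D influences adverse event X differently per scenario
        d = NodeSpec("D", ("act", "wait"))
        x = NodeSpec("X", ("bad", "ok"), parents=("D",))

        def scenario(p_act, p_wait):
            return build_network(
                [d, x],
                [
                    Cpt("D", {(): (0.5, 0.5)}),
                    Cpt("X", {("act",): (p_act, 1 - p_act),
                              ("wait",): (p_wait, 1 - p_wait)}),
                ],
            )

        return ModelSet(
            members=(("s1", scenario(0.1, 0.2)), ("s2", scenario(0.4, 0.3)))
        )

    def test_minimax_ranking_from_decision_matrix(self):
        """Matrix [[0.1, 0.4], [0.2, 0.3]] ranks decision 2 before 1 by
        worst cases (0.3, 0.4)."""
        ms = self._two_scenario_set()
        decisions = [
            ("act", (Evidence.hard("D", "act"),)),
            ("wait", (Evidence.hard("D", "wait"),)),
        ]
        res = robust_scan(ms, decisions, Query("X", ("bad",)))
        assert res.worst_case["act"] == pytest.approx(0.4)
        assert res.worst_case["wait"] == pytest.approx(0.3)
        assert res.ranking == ("wait", "act")

    def test_matrix_cells_equal_individual_queries(self):
        ms = self._two_scenario_set()
        decisions = [("act", (Evidence.hard("D", "act"),))]
        res = robust_scan(ms, decisions, Query("X", ("bad",)))
        for slabel, m in ms.members:
            q = Query("X", ("bad",), (Evidence.hard("D", "act"),))
            assert res.matrix[("act", slabel)] == pytest.approx(
                eliminate_query(m, q), abs=1e-15
            )

    def test_single_scenario_degenerates_to_plain_ranking(self):
        ms = ModelSet(members=(self._two_scenario_set().members[0],))
        decisions = [
            ("act", (Evidence.hard("D", "act"),)),
            ("wait", (Evidence.hard("D", "wait"),)),
        ]
        res = robust_scan(ms, decisions, Query("X", ("bad",)))
        assert res.ranking == ("act", "wait")  # 0.1 < 0.2

    def test_inconsistent_decision_flagged_and_excluded(self):
        d = NodeSpec("D", ("act", "wait"))
        x = NodeSpec("X", ("bad", "ok"), parents=("D",))
        m = build_network(
            [d, x],
            [
                Cpt("D", {(): (0.0, 1.0)}),  # "act" impossible in this scenario
                Cpt("X", {("act",): (0.2, 0.8), ("wait",): (0.5, 0.5)}),
            ],
        )
        ms = ModelSet(members=(("s1", m),))
        decisions = [
            ("act", (Evidence.hard("D", "act"),)),
            ("wait", (Evidence.hard("D", "wait"),)),
        ]
        with pytest.warns(UserWarning, match="excluded"):
            res = robust_scan(ms, decisions, Query("X", ("bad",)))
        assert res.excluded == ("act",)
        assert res.matrix[("act", "s1")] is None
        assert res.ranking == ("wait",)
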