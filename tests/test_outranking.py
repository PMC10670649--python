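"""PROMETHEE core: preference indices, flows, partial and complete orders."""

import numpy as np
import pytest

from fpromethee import (
    Criterion,
    DecisionMatrix,
    FlowTable,
    entering_flow,
    leaving_flow,
    make_tfn,
    net_flow,
    preference_index,
    preference_matrix,
    promethee1,
    promethee2,
    run_full_analysis,
    unicriterion_net_flows,
)
from fpromethee.outranking import DecisionMatrixError

from conftest import naive_flows, naive_preference_matrix, random_matrix


class TestPreferenceIndex:
    def test_identical_rows_give_zero(self):
        crit = (Criterion(id="c1", weight=make_tfn(1, 1, 1)),)
        m = DecisionMatrix(("A", "B"), crit, np.array([[3.0], [3.0]]))
        pi = preference_matrix(m)
        assert np.all(pi == 0)

    def test_dominating_by_far_with_usual_function_gives_one(self):
        from fpromethee.preference import PreferenceFunctionSpec

        crit = tuple(
            Criterion(
                id=f"c{j}",
                weight=make_tfn(0.5, 0.5, 0.5),
                pf=PreferenceFunctionSpec(family="usual"),
            )
            for j in range(2)
        )
        m = DecisionMatrix(("A", "B"), crit, np.array([[10.0, 10.0], [1.0, 1.0]]))
        assert preference_index("A", "B", m) == pytest.approx(1.0)
        assert preference_index("B", "A", m) == 0.0

    def test_toy_matrix_matches_triple_loop(self, toy_matrix):
        pi = preference_matrix(toy_matrix)
        oracle = np.array(naive_preference_matrix(toy_matrix))
        assert np.allclose(pi, oracle, atol=1e-12)

    def test_diagonal_zero_and_unit_interval(self, toy_matrix):
        pi = preference_matrix(toy_matrix)
        assert np.all(np.diag(pi) == 0)
        assert np.all((pi >= 0) & (pi <= 1))

    def test_self_comparison_rejected(self, toy_matrix):
        with pytest.raises(DecisionMatrixError):
            preference_index("A", "A", toy_matrix)


class TestFlows:
    def test_two_alternatives_single_term(self):
        pi = np.array([[0.0, 0.4], [0.1, 0.0]])
        assert leaving_flow(pi)[0] == pytest.approx(0.4)
        assert entering_flow(pi)[0] == pytest.approx(0.1)

    def test_constant_pi_gives_constant_flows(self):
        pi = np.full((5, 5), 0.3)
        np.fill_diagonal(pi, 0)
        assert np.allclose(leaving_flow(pi), 0.3)
        assert np.allclose(entering_flow(pi), 0.3)

    def test_symmetric_pi_equalizes_flows(self):
        rng = np.random.default_rng(7)
        pi = rng.uniform(0, 1, (4, 4))
        pi = (pi + pi.T) / 2
        np.fill_diagonal(pi, 0)
        assert np.allclose(leaving_flow(pi), entering_flow(pi))

    def test_random_pi_matches_double_loop(self):
        rng = np.random.default_rng(11)
        pi = rng.uniform(0, 1, (4, 4))
        np.fill_diagonal(pi, 0)
        plus, minus = naive_flows(pi.tolist())
        assert np.allclose(leaving_flow(pi), plus, atol=1e-12)
        assert np.allclose(entering_flow(pi), minus, atol=1e-12)

    def test_single_alternative_rejected(self):
        with pytest.raises(ValueError):
            leaving_flow(np.zeros((1, 1)))

    @pytest.mark.parametrize(
        "plus, minus, expected",
        [(0.0064, 0.0001, 0.0063), (0.0029, 0.0077, -0.0048), (0.3, 0.3, 0.0)],
    )
    def test_net_flow_difference(self, plus, minus, expected):
        assert net_flow(plus, minus) == pytest.approx(expected, abs=1e-12)


class TestPromethee1:
    def _flows(self, pairs):
        labels = tuple(chr(ord("a") + i) for i in range(len(pairs)))
        plus = np.array([p for p, _ in pairs])
        minus = np.array([m for _, m in pairs])
        return FlowTable(labels, plus, minus)

    def test_clear_preference(self):
        order = promethee1(self._flows([(0.5, 0.1), (0.3, 0.2)]), 1e-9)
        assert order.relation("a", "b") == "P"
        assert order.relation("b", "a") == "P-"

    def test_equal_leaving_lower_entering_is_preference(self):
        order = promethee1(self._flows([(0.5, 0.1), (0.5, 0.2)]), 1e-9)
        assert order.relation("a", "b") == "P"

    def test_identical_flows_are_indifferent(self):
        order = promethee1(self._flows([(0.4, 0.2), (0.4, 0.2)]), 1e-9)
        assert order.relation("a", "b") == "I"
        assert order.relation("b", "a") == "I"

    def test_crossed_dominance_is_incomparable(self):
        order = promethee1(self._flows([(0.5, 0.4), (0.3, 0.1)]), 1e-9)
        assert order.relation("a", "b") == "R"
        assert order.relation("b", "a") == "R"

    def test_every_ordered_pair_classified_with_consistent_symmetry(self):
        rng = np.random.default_rng(3)
        flows = self._flows([(rng.random(), rng.random()) for _ in range(6)])
        order = promethee1(flows, 1e-9)
        inverse = {"P": "P-", "P-": "P", "I": "I", "R": "R"}
        n = len(flows.alternatives)
        for i in range(n):
            assert order.relations[i, i] == "self"
            for j in range(n):
                if i == j:
                    continue
                rij = str(order.relations[i, j])
                assert rij in inverse
                assert str(order.relations[j, i]) == inverse[rij]


class TestPromethee2:
    def test_ranks_descending_by_net_flow(self):
        flows = FlowTable(
            ("a", "b", "c"), np.array([0.1, 0.5, 0.3]), np.array([0.4, 0.0, 0.3])
        )
        ranking = promethee2(flows, 1e-9)
        assert ranking.order == ("b", "c", "a")
        assert [r for r, _, _ in ranking.rows] == [1, 2, 3]

    def test_competition_ranking_for_ties(self):
        flows = FlowTable(
            ("a", "b", "c", "d"),
            np.array([0.5, 0.4, 0.4, 0.1]),
            np.zeros(4),
        )
        ranking = promethee2(flows, 1e-9)
        assert [r for r, _, _ in ranking.rows] == [1, 2, 2, 4]

    def test_random_flows_match_sort_oracle(self):
        rng = np.random.default_rng(5)
        net = rng.normal(size=5)
        flows = FlowTable(
            tuple(f"x{i}" for i in range(5)), net, np.zeros(5)
        )
        ranking = promethee2(flows, 0.0)
        expected = [f"x{i}" for i in np.argsort(-net)]
        assert list(ranking.order) == expected


class TestUnicriterionProfile:
    def test_single_criterion_profile_equals_net_flow(self):
        crit = (Criterion(id="c1", weight=make_tfn(1, 1, 1)),)
        m = DecisionMatrix(
            ("A", "B", "C"), crit, np.array([[1.0], [2.0], [4.0]])
        )
        res = run_full_analysis(m)
        profile = unicriterion_net_flows(m)
        assert np.allclose(profile["c1"].to_numpy(), res.flows.phi_net, atol=1e-12)

    def test_weighted_sum_reproduces_net_flow(self):
        rng = np.random.default_rng(17)
        m = random_matrix(rng, n=6, k=4)
        res = run_full_analysis(m)
        profile = unicriterion_net_flows(m)
        w = res.weights.as_array()
        recomposed = profile.to_numpy() @ w
        assert np.allclose(recomposed, res.flows.phi_net, atol=1e-12)

    def test_worst_alternative_has_nonpositive_contribution(self):
        crit = (
            Criterion(id="c1", weight=make_tfn(0.5, 0.5, 0.5)),
            Criterion(id="c2", weight=make_tfn(0.5, 0.5, 0.5)),
        )
        m = DecisionMatrix(
            ("A", "B", "C"),
            crit,
            np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 1.0]]),
        )
        profile = unicriterion_net_flows(m)
        assert profile.loc["A", "c1"] <= 0  # worst on c1 everywhere
        assert profile.loc["C", "c2"] <= 0


class TestFullAnalysis:
    def test_zero_sum_net_flows(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            m = random_matrix(rng, n=7, k=5)
            res = run_full_analysis(m)
            assert abs(res.flows.phi_net.sum()) < 1e-10

    def test_single_criterion_ranking_sorts_by_value(self):
        crit = (Criterion(id="cost", direction="minimize", weight=make_tfn(1, 1, 1)),)
        m = DecisionMatrix(
            ("A", "B", "C", "D"),
            crit,
            np.array([[8.0], [2.0], [5.0], [3.0]]),
        )
        res = run_full_analysis(m)
        assert res.ranking.order == ("B", "D", "C", "A")

    def test_vectorized_engine_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            m = random_matrix(rng)
            pi = preference_matrix(m)
            oracle = np.array(naive_preference_matrix(m))
            assert np.allclose(pi, oracle, atol=1e-12)

    def test_incomplete_matrix_rejected_with_coordinates(self):
        crit = (Criterion(id="c1", weight=make_tfn(1, 1, 1)),)
        with pytest.raises(DecisionMatrixError, match="c1"):
            DecisionMatrix(("A", "B"), crit, np.array([[1.0], [np.nan]]))
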