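"""One-way/two-way sweeps, threshold finding, and Monte-Carlo calibration."""

import numpy as np
import pytest

from oncomda.evaluation import fold_back
from oncomda.sensitivity import (
    Beta,
    ParameterRef,
    Point,
    UncertaintySpec,
    Uniform,
    monte_carlo,
    one_way,
    set_parameter,
    threshold,
    two_way,
)
from oncomda.tree_model import DomainError, ParameterError, iter_nodes, resolve_path
from oncomda.tree_model import ChanceNode
from conftest import make_basic_tree

CURE_B = ParameterRef("treatment B", "cure")
CURE_A = ParameterRef("treatment A", "cure")


class TestSetParameter:
    def test_two_branch_complement_moves(self, basic_tree):
        set_parameter(basic_tree, CURE_B, 0.25)
        node = resolve_path(basic_tree, "treatment B")
        assert node.branches[0].p == 0.25
        assert node.branches[1].p == pytest.approx(0.75)

    def test_multibranch_rescales_proportionally(self):
        from oncomda.tree_model import (
            ChanceBranch,
            DecisionNode,
            DecisionOption,
            DecisionTree,
            TerminalNode,
        )

        node = ChanceNode(
            "e",
            [
                ChanceBranch("a", 0.2, TerminalNode("a", 1.0)),
                ChanceBranch("b", 0.2, TerminalNode("b", 0.5)),
                ChanceBranch("c", 0.6, TerminalNode("c", 0.0)),
            ],
        )
        tree = DecisionTree(DecisionNode("r", [
            DecisionOption("x", node), DecisionOption("y", TerminalNode("t", 0.0))]))
        set_parameter(tree, ParameterRef("x", "a"), 0.5)
        ps = [b.p for b in node.branches]
        assert ps == pytest.approx([0.5, 0.125, 0.375])
        assert sum(ps) == pytest.approx(1.0)

    def test_out_of_range_names_the_node(self, basic_tree):
        with pytest.raises(DomainError) as err:
            set_parameter(basic_tree, CURE_B, 1.2)
        assert "treatment B" in str(err.value)

    def test_unresolvable_reference(self, basic_tree):
        with pytest.raises(ParameterError):
            set_parameter(basic_tree, ParameterRef("nowhere", "cure"), 0.5)


class TestOneWay:
    def test_parameter_locality(self, basic_tree):
        result = one_way(basic_tree, CURE_B, grid=np.linspace(0, 1, 11))
        a_values = result.option_values["treatment A"]
        assert all(v == pytest.approx(0.7) for v in a_values)

    def test_crossing_detected_at_known_threshold(self, basic_tree):
        result = one_way(basic_tree, CURE_B)
        assert len(result.thresholds) == 1
        assert result.thresholds[0].values[0] == pytest.approx(0.7, abs=1e-9)

    def test_eu_affine_in_chance_probability(self):
        # fold-back EU is affine in any single chance probability: a linear
        # fit across the grid leaves essentially no residual
        tree = make_basic_tree(u_cure=0.9, u_no_cure=0.15)
        result = one_way(tree, CURE_B)
        x = np.asarray(result.grid)
        for values in result.option_values.values():
            y = np.asarray(values)
            coeffs = np.polyfit(x, y, 1)
            assert np.max(np.abs(np.polyval(coeffs, x) - y)) < 1e-10

    def test_single_point_matches_manual_substitution(self, basic_tree):
        result = one_way(basic_tree, CURE_B, grid=[0.42])
        manual = basic_tree.copy()
        set_parameter(manual, CURE_B, 0.42)
        expected = fold_back(manual).option_values
        for opt, values in result.option_values.items():
            assert values[0] == pytest.approx(expected[opt], abs=1e-15)


class TestThreshold:
    def test_closed_form_crossing(self, basic_tree):
        result = threshold(basic_tree, CURE_B, "treatment A", "treatment B")
        assert result.found
        assert result.values[0] == pytest.approx(0.7, abs=1e-10)

    def test_dominated_option_yields_no_threshold(self):
        tree = make_basic_tree(u_cure=1.0)
        # option A utility stays 1 per cure while B's cure is worth 0.5:
        # B can never catch up on [0, 1] when A sits at 0.7
        resolve_path(tree, "treatment B/cure").value = 0.5
        result = threshold(tree, CURE_B, "treatment A", "treatment B")
        assert not result.found and result.values == []

    def test_matches_analytic_root_on_random_trees(self):
        # EU_B(p) = u_cure * p + u_nocure * (1 - p); solve for EU_A analytically
        rng = np.random.default_rng(5)
        for _ in range(25):
            u_cure, u_nocure = sorted(rng.uniform(0, 1, size=2))[::-1]
            p_a = float(rng.uniform(0, 1))
            tree = make_basic_tree(p_cure_a=p_a, u_cure=u_cure, u_no_cure=u_nocure)
            eu_a = u_cure * p_a + u_nocure * (1 - p_a)
            result = threshold(tree, CURE_B, "treatment A", "treatment B")
            if u_cure == u_nocure:
                continue
            analytic = (eu_a - u_nocure) / (u_cure - u_nocure)
            if 0 <= analytic <= 1:
                assert result.found
                found = result.values[0]
                # the stopping rule is on the EU gap, so compare there
                eu_gap = abs(u_cure * found + u_nocure * (1 - found) - eu_a)
                assert eu_gap <= 1e-9
            else:
                assert not result.found


class TestTwoWay:
    def test_row_recovers_one_way(self, basic_tree):
        grid = list(np.linspace(0, 1, 11))
        tw = two_way(basic_tree, CURE_A, CURE_B, [0.7], grid)
        ow = one_way(basic_tree, CURE_B, grid=grid)
        assert tw.winners[0] == ow.winners

    def test_degenerate_grid_matches_fold_back(self, basic_tree):
        tw = two_way(basic_tree, CURE_A, CURE_B, [0.7], [0.5])
        assert tw.winners == [[fold_back(basic_tree).optimal_option]]

    def test_decision_boundary_monotone(self, basic_tree):
        # EU(A) rises in P(cure|A) and EU(B) in P(cure|B): once A wins along
        # a row of increasing P(cure|A), it keeps winning
        grid = list(np.linspace(0, 1, 21))
        tw = two_way(basic_tree, CURE_B, CURE_A, grid, grid)
        for row in tw.winners:  # row: fixed P(cure|B), varying P(cure|A)
            flips = sum(1 for a, b in zip(row, row[1:]) if a != b)
            assert flips <= 1


class TestMonteCarlo:
    def test_point_masses_reproduce_deterministic_winner(self, basic_tree):
        spec = (
            UncertaintySpec()
            .add_probability("treatment A", "cure", Point(0.7))
            .add_probability("treatment B", "cure", Point(0.5))
        )
        result = monte_carlo(basic_tree, spec, n=500, seed=1)
        assert result.win_proportions["treatment A"] == 1.0
        assert result.win_proportions["treatment B"] == 0.0

    def test_symmetric_options_split_evenly(self, basic_tree):
        # mirror-image uniforms; with n = 10,000 the win proportions must
        # fall inside the 99% binomial interval around 1/2
        spec = (
            UncertaintySpec()
            .add_probability("treatment A", "cure", Uniform(0.3, 0.9))
            .add_probability("treatment B", "cure", Uniform(0.3, 0.9))
        )
        result = monte_carlo(basic_tree, spec, n=10_000, seed=20260)
        half_width = 2.5758 * np.sqrt(0.25 / 10_000)
        assert abs(result.win_proportions["treatment A"] - 0.5) < half_width

    def test_win_proportion_tracks_uniform_cdf(self, basic_tree):
        # A wins iff uniform(0,1) P(cure|A) exceeds fixed EU(B) = 0.3, so the
        # win proportion estimates P(U > 0.3) = 0.7
        spec = UncertaintySpec().add_probability("treatment A", "cure", Uniform(0, 1))
        tree = make_basic_tree(p_cure_b=0.3)
        result = monte_carlo(tree, spec, n=10_000, seed=99)
        half_width = 2.5758 * np.sqrt(0.7 * 0.3 / 10_000)
        assert abs(result.win_proportions["treatment A"] - 0.7) < half_width

    def test_deterministic_given_seed(self, basic_tree):
        spec = (
            UncertaintySpec()
            .add_probability("treatment A", "cure", Beta(4, 2))
            .add_value("treatment B/cure", Uniform(0.5, 1.0))
        )
        r1 = monte_carlo(basic_tree, spec, n=300, seed=7)
        r2 = monte_carlo(basic_tree, spec, n=300, seed=7)
        assert r1 == r2
        r3 = monte_carlo(basic_tree, spec, n=300, seed=8)
        assert r3.win_proportions != r1.win_proportions or r3.eu_summary != r1.eu_summary

    def test_win_proportions_sum_to_one_and_mean_in_hull(self, basic_tree):
        spec = (
            UncertaintySpec()
            .add_probability("treatment A", "cure", Uniform(0, 1))
            .add_probability("treatment B", "cure", Beta(2, 2))
        )
        result = monte_carlo(basic_tree, spec, n=2_000, seed=3)
        assert sum(result.win_proportions.values()) == pytest.approx(1.0, abs=1e-9)
        for summary in result.eu_summary.values():
            assert summary["q2.5"] <= summary["mean"] <= summary["q97.5"]

    def test_dirichlet_keeps_node_coherent(self):
        from oncomda.tree_model import (
            ChanceBranch,
            DecisionNode,
            DecisionOption,
            DecisionTree,
            TerminalNode,
        )

        node = ChanceNode(
            "e",
            [
                ChanceBranch("a", 0.3, TerminalNode("a", 1.0)),
                ChanceBranch("b", 0.3, TerminalNode("b", 0.5)),
                ChanceBranch("c", 0.4, TerminalNode("c", 0.0)),
            ],
        )
        tree = DecisionTree(DecisionNode("r", [
            DecisionOption("x", node), DecisionOption("y", TerminalNode("t", 0.4))]))
        spec = UncertaintySpec().add_dirichlet("x", [3, 3, 4])

        seen_sums = []
        import oncomda.sensitivity as sens

        original = sens.fold_back

        def spy(t):
            n = resolve_path(t, "x")
            seen_sums.append(sum(b.p for b in n.branches))
            return original(t)

        sens.fold_back = spy
        try:
            monte_carlo(tree, spec, n=200, seed=4)
        finally:
            sens.fold_back = original
        assert seen_sums and all(abs(s - 1.0) <= 1e-12 for s in seen_sums)

    def test_multibranch_independent_entries_demand_dirichlet(self):
        from oncomda.tree_model import (
            ChanceBranch,
            DecisionNode,
            DecisionOption,
            DecisionTree,
            TerminalNode,
        )

        node = ChanceNode(
            "e",
            [
                ChanceBranch("a", 0.3, TerminalNode("a", 1.0)),
                ChanceBranch("b", 0.3, TerminalNode("b", 0.5)),
                ChanceBranch("c", 0.4, TerminalNode("c", 0.0)),
            ],
        )
        tree = DecisionTree(DecisionNode("r", [
            DecisionOption("x", node), DecisionOption("y", TerminalNode("t", 0.4))]))
        spec = (
            UncertaintySpec()
            .add_probability("x", "a", Uniform(0, 1))
            .add_probability("x", "b", Uniform(0, 1))
        )
        with pytest.raises(ParameterError):
            monte_carlo(tree, spec, n=10, seed=0)

    def test_seed_is_required(self, basic_tree):
        spec = UncertaintySpec().add_probability("treatment A", "cure", Uniform(0, 1))
        with pytest.raises(ParameterError):
            monte_carlo(basic_tree, spec, n=10)

    def test_ordering_constraint_respected(self, basic_tree):
        spec = (
            UncertaintySpec()
            .add_value("treatment A/cure", Uniform(0, 1))
            .add_value("treatment B/cure", Uniform(0, 1))
            .add_ordering("treatment A/cure", "treatment B/cure")
        )
        import oncomda.sensitivity as sens

        recorded = []
        original = sens.fold_back

        def spy(t):
            recorded.append(
                (resolve_path(t, "treatment A/cure").value,
                 resolve_path(t, "treatment B/cure").value)
            )
            return original(t)

        sens.fold_back = spy
        try:
            monte_carlo(basic_tree, spec, n=200, seed=11)
        finally:
            sens.fold_back = original
        assert recorded and all(a <= b for a, b in recorded)
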