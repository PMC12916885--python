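"""Template builders: hand fold-backs, degeneration lattice, validity."""

import pytest

from oncomda.evaluation import fold_back, risk_analysis
from oncomda import evidence as ev
from oncomda.evidence import WaterfallData, waterfall_probability
from oncomda.sensitivity import ParameterRef, threshold
from oncomda.templates import (
    AdjuvantParams,
    AdvancedDiseaseOption,
    AdvancedDiseaseParams,
    CytoreductionParams,
    ExpandedTradeoffParams,
    OrganTradeoffParams,
    SurveillanceParams,
    adjuvant_tree,
    advanced_disease_tree,
    cytoreduction_tree,
    expanded_tradeoff_tree,
    followup_subtree,
    organ_tradeoff_tree,
    surveillance_tree,
)
from oncomda.tree_model import DomainError, iter_nodes, validate, ChanceNode, TerminalNode


def all_template_trees():
    basic = OrganTradeoffParams(0.9, 0.8, 0.9)
    return [
        organ_tradeoff_tree(basic),
        expanded_tradeoff_tree(ExpandedTradeoffParams(basic, 0.3, 0.7, 0.5)),
        adjuvant_tree(AdjuvantParams(0.5, 0.2)),
        adjuvant_tree(AdjuvantParams(0.5, 0.2, p_fatal_toxicity=0.02)),
        cytoreduction_tree(CytoreductionParams(0.4, 0.8, 0.85, 0.3, 0.6)),
        surveillance_tree(SurveillanceParams(0.4, 0.8, 0.9, 0.85, 0.8)),
        advanced_disease_tree(
            AdvancedDiseaseParams(
                (AdvancedDiseaseOption.from_benefit("chemo", 0.3, 12.0, 2.0),),
                bsc_value=2.0,
            )
        ),
    ]


class TestTemplateValidity:
    @pytest.mark.parametrize("tree", all_template_trees(),
                             ids=lambda t: t.metadata["scenario"])
    def test_every_template_validates(self, tree):
        assert validate(tree).is_valid

    @pytest.mark.parametrize("tree", all_template_trees(),
                             ids=lambda t: t.metadata["scenario"])
    def test_chance_nodes_and_risk_rows_conserve_probability(self, tree):
        for _, node in iter_nodes(tree):
            if isinstance(node, ChanceNode):
                assert sum(b.p for b in node.branches) == pytest.approx(1.0, abs=1e-9)
        for row in risk_analysis(tree).profiles.values():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)


class TestOrganTradeoff:
    def test_hand_folded_expected_utilities(self):
        tree = organ_tradeoff_tree(OrganTradeoffParams(0.9, 0.8, 0.9))
        eu = fold_back(tree).option_values
        assert eu["radical treatment"] == pytest.approx(0.81)
        assert eu["conservative treatment"] == pytest.approx(0.8)

    def test_no_quality_penalty_reduces_to_cure_comparison(self):
        tree = organ_tradeoff_tree(OrganTradeoffParams(0.9, 0.8, 1.0))
        assert fold_back(tree).optimal_option == "radical treatment"
        tree = organ_tradeoff_tree(OrganTradeoffParams(0.7, 0.8, 1.0))
        assert fold_back(tree).optimal_option == "conservative treatment"

    def test_indifference_utility_threshold(self):
        # EU(radical) = p_rad * u; EU(cons) = p_cons: indifference at u* = p_cons/p_rad
        tree = organ_tradeoff_tree(OrganTradeoffParams(0.9, 0.72, 0.5))
        result = threshold(
            tree,
            ParameterRef("radical treatment/cure", None),
            "radical treatment",
            "conservative treatment",
        )
        assert result.found
        assert result.values[0] == pytest.approx(0.72 / 0.9, abs=1e-8)


class TestExpandedTradeoff:
    BASIC = OrganTradeoffParams(0.9, 0.8, 0.9)

    def test_degenerates_to_basic_at_zero_local_relapse(self):
        expanded = expanded_tradeoff_tree(ExpandedTradeoffParams(self.BASIC, 0.0, 0.7, 0.5))
        basic = organ_tradeoff_tree(self.BASIC)
        assert fold_back(expanded).option_values["conservative treatment"] == \
            fold_back(basic).option_values["conservative treatment"]
        assert fold_back(expanded).option_values["radical treatment"] == \
            fold_back(basic).option_values["radical treatment"]

    def test_relapse_path_hand_fold_back(self):
        # full rescue with radical-arm cure rate: relapse path worth
        # p_cure_radical * u_organ_loss
        expanded = expanded_tradeoff_tree(
            ExpandedTradeoffParams(self.BASIC, 1.0, 1.0, self.BASIC.p_cure_radical)
        )
        eu = fold_back(expanded).option_values
        assert eu["conservative treatment"] == pytest.approx(0.9 * 0.9)

    def test_hopeless_rescue_contributes_nothing(self):
        expanded = expanded_tradeoff_tree(ExpandedTradeoffParams(self.BASIC, 0.3, 0.0, 0.0))
        eu = fold_back(expanded).option_values
        assert eu["conservative treatment"] == pytest.approx(0.7 * 0.8 * 1.0)


class TestAdjuvant:
    @pytest.mark.parametrize("baseline_cure, arr", [(0.5, 0.10), (0.95, 0.01)])
    def test_risk_analysis_shows_absolute_risk_reduction(self, baseline_cure, arr):
        tree = adjuvant_tree(AdjuvantParams(baseline_cure, 0.2))
        profiles = risk_analysis(tree).profiles
        realized = (
            profiles["surgery plus adjuvant therapy"]["cure"]
            - profiles["surgery alone"]["cure"]
        )
        assert realized == pytest.approx(arr, abs=1e-12)

    def test_fatal_toxicity_hand_fold_back(self):
        tree = adjuvant_tree(AdjuvantParams(0.5, 0.2, p_fatal_toxicity=0.02))
        eu = fold_back(tree).option_values
        assert eu["surgery plus adjuvant therapy"] == pytest.approx(0.98 * 0.6)

    def test_degenerates_at_zero_toxicity(self):
        toxic = adjuvant_tree(AdjuvantParams(0.5, 0.2, p_fatal_toxicity=0.0))
        plain = adjuvant_tree(AdjuvantParams(0.5, 0.2))
        assert fold_back(toxic).option_values == fold_back(plain).option_values


class TestCytoreduction:
    def test_certain_regression_degenerates(self):
        tree = cytoreduction_tree(CytoreductionParams(1.0, 0.8, 0.85, 0.3, 0.6,
                                                      u_conservative=0.95))
        eu = fold_back(tree).option_values
        assert eu["cytoreduction then surgery"] == pytest.approx(0.8 * 0.95)

    def test_salvage_equal_to_upfront_only_differs_on_regression_branch(self):
        # with resectability never lost and salvage cure = upfront mutilating
        # cure, the insufficient-regression branch equals the mutilating arm
        p = CytoreductionParams(0.4, 0.8, 0.85, 0.0, 0.85)
        tree = cytoreduction_tree(p)
        eu = fold_back(tree).option_values
        mutilating = eu["mutilating surgery now"]
        expected_cyto = 0.4 * (0.8 * p.u_conservative) + 0.6 * mutilating
        assert eu["cytoreduction then surgery"] == pytest.approx(expected_cyto)

    def test_waterfall_probability_feeds_unchanged(self):
        data = WaterfallData([-80, -60, -50, -50, -30, -10, 0, 10, 25, 40])
        p_reg = waterfall_probability(data, 50)
        tree = cytoreduction_tree(CytoreductionParams(p_reg, 0.8, 0.85, 0.3, 0.6))
        from oncomda.tree_model import resolve_path

        node = resolve_path(tree, "cytoreduction then surgery")
        assert node.branches[0].p == p_reg == pytest.approx(0.4)


class TestSurveillance:
    def test_indolent_limit(self):
        tree = surveillance_tree(SurveillanceParams(0.0, 0.8, 0.9, 0.85, 0.8))
        assert fold_back(tree).option_values["active surveillance"] == pytest.approx(1.0)

    def test_certain_evolution_reduces_to_delayed_subtree(self):
        params = SurveillanceParams(1.0, 0.8, 0.9, 0.85, 0.8)
        tree = surveillance_tree(params)
        eu = fold_back(tree).option_values
        assert eu["active surveillance"] == pytest.approx(0.8 * 0.85 * 0.8)

    def test_surveillance_weakly_dominates_when_never_penalized(self):
        # feasible delayed treatment as good as immediate, and no morbidity
        # under surveillance: waiting cannot lose
        params = SurveillanceParams(0.4, 1.0, 0.85, 0.85, 0.8, u_no_treatment_morbidity=1.0)
        eu = fold_back(surveillance_tree(params)).option_values
        assert eu["active surveillance"] >= eu["immediate treatment"]


class TestAdvancedDisease:
    def test_hand_folded_expected_durations(self):
        tree = advanced_disease_tree(
            AdvancedDiseaseParams(
                (AdvancedDiseaseOption.from_benefit("therapy", 0.3, 12.0, 2.0),),
                bsc_value=2.0,
            )
        )
        eu = fold_back(tree).option_values
        assert eu["therapy"] == pytest.approx(0.3 * 12 + 0.7 * 2)
        assert eu["best supportive care"] == pytest.approx(2.0)

    def test_no_benefit_collapses_to_non_benefit_terminal(self):
        tree = advanced_disease_tree(
            AdvancedDiseaseParams(
                (AdvancedDiseaseOption.from_benefit("therapy", 0.0, 12.0, 2.0),),
                bsc_value=1.0,
            )
        )
        assert fold_back(tree).option_values["therapy"] == pytest.approx(2.0)

    def test_pfs_bins_feed_multibranch_node(self):
        from oncomda.evidence import SurvivalCurve, discretize_pfs

        curve = SurvivalCurve(times=[0, 6, 12], survival=[1.0, 0.5, 0.2])
        bins = discretize_pfs(curve, [6, 12])
        option = AdvancedDiseaseOption(
            "therapy", tuple((b.label, b.probability, b.duration) for b in bins)
        )
        tree = advanced_disease_tree(AdvancedDiseaseParams((option,), bsc_value=2.0))
        node = tree.root.options[0].child
        assert isinstance(node, ChanceNode) and len(node.branches) == 3
        assert sum(b.p for b in node.branches) == pytest.approx(1.0)

    def test_utility_measure_rejected(self):
        with pytest.raises(DomainError):
            advanced_disease_tree(
                AdvancedDiseaseParams(
                    (AdvancedDiseaseOption.from_benefit("t", 0.3, 12.0, 2.0),),
                    bsc_value=2.0,
                    measure="utility",
                )
            )


class TestFollowupSubtree:
    def test_four_branch_probabilities(self):
        node = followup_subtree(0.2, ev.TestCharacteristics(0.9, 0.8))
        probs = {b.label: b.p for b in node.branches}
        assert probs["relapse, detected"] == pytest.approx(0.18)
        assert probs["relapse, missed"] == pytest.approx(0.02)
        assert probs["no relapse, false alarm"] == pytest.approx(0.16)
        assert probs["no relapse, reassured"] == pytest.approx(0.64)

    def test_window_probability_feeds_unchanged(self):
        from oncomda.evidence import SurvivalCurve, event_probability_in_window

        curve = SurvivalCurve(times=[0, 12, 24], survival=[1.0, 0.8, 0.6])
        p = event_probability_in_window(curve, 12, 24)
        node = followup_subtree(p, ev.TestCharacteristics(0.9, 0.8))
        assert node.branches[0].p == pytest.approx(p * 0.9)

    def test_perfect_test_is_effectively_two_branch(self):
        node = followup_subtree(0.2, ev.TestCharacteristics(1.0, 1.0))
        nonzero = [b for b in node.branches if b.p > 0]
        assert len(nonzero) == 2


class TestRiskEuConsistency:
    def test_binary_utilities_make_eu_equal_cure_mass(self):
        # with all utilities in {0,1}, EU equals the probability mass
        # flowing into utility-1 terminals
        basic = OrganTradeoffParams(0.9, 0.8, 1.0, u_cure_organ_preserved=1.0)
        for tree in (
            organ_tradeoff_tree(basic),
            expanded_tradeoff_tree(ExpandedTradeoffParams(basic, 0.3, 0.7, 0.5)),
            adjuvant_tree(AdjuvantParams(0.5, 0.2, p_fatal_toxicity=0.02)),
        ):
            eu = fold_back(tree).option_values
            result = risk_analysis(tree)
            # sum risk mass over outcomes whose terminals carry value 1
            one_outcomes = {
                node.outcome
                for _, node in iter_nodes(tree)
                if isinstance(node, TerminalNode) and node.value == 1.0
            }
            for opt, row in result.profiles.items():
                mass = sum(p for o, p in row.items() if o in one_outcomes)
                assert eu[opt] == pytest.approx(mass, abs=1e-12)
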