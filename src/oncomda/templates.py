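"""Parameterized builders for six recurring oncology decision scenarios.

Each builder takes a small bundle of patient-specific probabilities and
utilities and returns a validated :class:`~oncomda.tree_model.DecisionTree`
ready for fold-back, risk analysis, or sensitivity analysis:

* quantity/quality trade-off (organ removal vs organ preservation), in a
  basic and an expanded form that adds local relapse and surgical rescue
  after conservative treatment;
* adjuvant therapy after surgery, optionally with a potentially fatal
  early toxicity;
* cytoreduction aiming to convert a mutilating resection into a
  conservative one;
* active surveillance / watchful waiting vs immediate treatment;
* treatment choice in advanced, non-curable disease, with options
  described by clinical-benefit bins (e.g. from a discretized
  progression-free-survival curve) against best supportive care;
* a follow-up chance subtree combining window relapse risk with the
  sensitivity/specificity of a surveillance exam.

Conventions shared by all builders: the intervention under consideration
is listed first (so fold-back tie-breaking is reproducible), cure
terminals with no quality penalty carry utility 1, and death/no-cure
terminals carry utility 0 unless a parameter says otherwise.  The richer
templates degenerate exactly to their simpler parents (expanded
trade-off at zero local-relapse risk; toxic adjuvant at zero fatal
toxicity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .evidence import TestCharacteristics, adjuvant_cure_probability, test_outcome_probabilities
from .tree_model import (
    ChanceBranch,
    ChanceNode,
    DecisionNode,
    DecisionOption,
    DecisionTree,
    DomainError,
    Node,
    TerminalNode,
    check_probability,
    validate,
)

__all__ = [
    "OrganTradeoffParams",
    "ExpandedTradeoffParams",
    "AdjuvantParams",
    "CytoreductionParams",
    "SurveillanceParams",
    "AdvancedDiseaseOption",
    "AdvancedDiseaseParams",
    "organ_tradeoff_tree",
    "expanded_tradeoff_tree",
    "adjuvant_tree",
    "cytoreduction_tree",
    "surveillance_tree",
    "advanced_disease_tree",
    "followup_subtree",
]


def _chance(label: str, *branches: Tuple[str, Optional[float], Node]) -> ChanceNode:
    return ChanceNode(label, [ChanceBranch(lbl, p, child) for lbl, p, child in branches])


def _cure_chance(label: str, p_cure: float, cure_terminal: TerminalNode,
                 no_cure_outcome: str = "no cure", no_cure_value: float = 0.0) -> ChanceNode:
    return _chance(
        label,
        ("cure", p_cure, cure_terminal),
        (no_cure_outcome, None, TerminalNode(no_cure_outcome, no_cure_value)),
    )


def _finish(root: DecisionNode, measure: str, scenario: str, **meta: object) -> DecisionTree:
    tree = DecisionTree(root=root, measure=measure, metadata={"scenario": scenario, **meta})
    validate(tree).raise_if_invalid()
    return tree


# ---------------------------------------------------------------------------
# Quantity/quality trade-off
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganTradeoffParams:
    """Radical (organ-removing) vs conservative (organ-preserving) treatment.

    ``u_cure_organ_loss`` is the patient's utility for cure at the price
    of the organ, typically elicited by the standard gamble; cure with
    the organ preserved is worth 1 and no cure 0 by default.
    """

    p_cure_radical: float
    p_cure_conservative: float
    u_cure_organ_loss: float
    u_cure_organ_preserved: float = 1.0
    u_no_cure: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_cure_radical", "p_cure_conservative", "u_cure_organ_loss",
                     "u_cure_organ_preserved", "u_no_cure"):
            check_probability(getattr(self, name), name)


def organ_tradeoff_tree(params: OrganTradeoffParams) -> DecisionTree:
    """Basic quantity/quality trade-off tree (radical listed first)."""
    root = DecisionNode(
        "treatment choice",
        [
            DecisionOption(
                "radical treatment",
                _cure_chance(
                    "outcome after radical treatment",
                    params.p_cure_radical,
                    TerminalNode("cure with organ loss", params.u_cure_organ_loss),
                    no_cure_value=params.u_no_cure,
                ),
            ),
            DecisionOption(
                "conservative treatment",
                _cure_chance(
                    "outcome after conservative treatment",
                    params.p_cure_conservative,
                    TerminalNode("cure with organ preserved", params.u_cure_organ_preserved),
                    no_cure_value=params.u_no_cure,
                ),
            ),
        ],
    )
    return _finish(root, "utility", "organ trade-off")


@dataclass(frozen=True)
class ExpandedTradeoffParams:
    """Trade-off with local relapse after conservative treatment.

    A local relapse after conservative treatment can be rescued by organ
    removal in a proportion of cases; the systemic outlook after a
    rescued relapse is a free parameter (``p_cure_after_rescue``) because
    it may range from nil to the original baseline or even above it.
    """

    basic: OrganTradeoffParams
    p_local_relapse_conservative: float
    p_rescue_by_organ_removal: float
    p_cure_after_rescue: float

    def __post_init__(self) -> None:
        for name in ("p_local_relapse_conservative", "p_rescue_by_organ_removal",
                     "p_cure_after_rescue"):
            check_probability(getattr(self, name), name)


def expanded_tradeoff_tree(params: ExpandedTradeoffParams) -> DecisionTree:
    """Expanded trade-off: conservative arm gains a local-relapse layer.

    At ``p_local_relapse_conservative = 0`` the conservative arm's EU
    equals the basic template's conservative arm.
    """
    b = params.basic
    rescue_subtree = _chance(
        "rescue by organ removal",
        (
            "rescued",
            params.p_rescue_by_organ_removal,
            _cure_chance(
                "outcome after rescue surgery",
                params.p_cure_after_rescue,
                TerminalNode("cure with organ loss", b.u_cure_organ_loss),
                no_cure_value=b.u_no_cure,
            ),
        ),
        ("not rescued", None, TerminalNode("no cure", b.u_no_cure)),
    )
    conservative = _chance(
        "local outcome after conservative treatment",
        ("local relapse", params.p_local_relapse_conservative, rescue_subtree),
        (
            "no local relapse",
            None,
            _cure_chance(
                "systemic outcome",
                b.p_cure_conservative,
                TerminalNode("cure with organ preserved", b.u_cure_organ_preserved),
                no_cure_value=b.u_no_cure,
            ),
        ),
    )
    root = DecisionNode(
        "treatment choice",
        [
            DecisionOption(
                "radical treatment",
                _cure_chance(
                    "outcome after radical treatment",
                    b.p_cure_radical,
                    TerminalNode("cure with organ loss", b.u_cure_organ_loss),
                    no_cure_value=b.u_no_cure,
                ),
            ),
            DecisionOption("conservative treatment", conservative),
        ],
    )
    return _finish(root, "utility", "expanded organ trade-off")


# ---------------------------------------------------------------------------
# Adjuvant therapy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjuvantParams:
    """Surgery alone vs surgery plus adjuvant therapy.

    The adjuvant arm's cure probability is derived from the baseline and
    the relative risk reduction: ``p + (1 - p) * rrr``.  An optional
    fatal-toxicity probability inserts an early-toxic-death branch ahead
    of the cure chance; an optional ``u_time_on_therapy`` discounts the
    adjuvant arm's cure terminal for the time spent on therapy.
    """

    p_cure_surgery_alone: float
    rrr: float
    p_fatal_toxicity: Optional[float] = None
    u_time_on_therapy: Optional[float] = None

    def __post_init__(self) -> None:
        check_probability(self.p_cure_surgery_alone, "p_cure_surgery_alone")
        check_probability(self.rrr, "rrr")
        if self.p_fatal_toxicity is not None:
            check_probability(self.p_fatal_toxicity, "p_fatal_toxicity")
        if self.u_time_on_therapy is not None:
            check_probability(self.u_time_on_therapy, "u_time_on_therapy")


def adjuvant_tree(params: AdjuvantParams) -> DecisionTree:
    """Adjuvant-therapy tree, with optional fatal early toxicity.

    With 1/0 utilities, risk analysis on this tree exhibits the absolute
    risk reduction: P(cure | adjuvant) - P(cure | surgery alone).  The
    fatal-toxicity variant keeps early toxic death as a distinct outcome
    label from relapse death, even though both carry utility 0, so risk
    analysis can tell them apart; at ``p_fatal_toxicity = 0`` its EU
    reduces exactly to the plain template's.
    """
    p_adj = adjuvant_cure_probability(params.p_cure_surgery_alone, params.rrr)
    u_cure_adj = 1.0 if params.u_time_on_therapy is None else params.u_time_on_therapy

    cure_chance_adj = _chance(
        "systemic outcome with adjuvant therapy",
        ("cure", p_adj, TerminalNode("cure", u_cure_adj)),
        ("relapse", None, TerminalNode("relapse", 0.0)),
    )
    if params.p_fatal_toxicity is None:
        adj_child: Node = cure_chance_adj
    else:
        adj_child = _chance(
            "early toxicity",
            ("fatal toxicity", params.p_fatal_toxicity,
             TerminalNode("early toxic death", 0.0)),
            ("survives therapy", None, cure_chance_adj),
        )
    root = DecisionNode(
        "adjuvant decision",
        [
            DecisionOption("surgery plus adjuvant therapy", adj_child),
            DecisionOption(
                "surgery alone",
                _chance(
                    "systemic outcome with surgery alone",
                    ("cure", params.p_cure_surgery_alone, TerminalNode("cure", 1.0)),
                    ("relapse", None, TerminalNode("relapse", 0.0)),
                ),
            ),
        ],
    )
    return _finish(root, "utility", "adjuvant therapy")


# ---------------------------------------------------------------------------
# Cytoreduction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytoreductionParams:
    """Mutilating surgery now vs cytoreduction aiming at conservative surgery.

    ``p_sufficient_regression`` is typically read off a waterfall plot at
    the clinically required regression threshold
    (:func:`~oncomda.evidence.waterfall_probability`).  If regression is
    insufficient, resectability may be lost on interval progression;
    otherwise a (wider) salvage resection is still attempted with
    ``p_cure_after_interval_progression``.  The mutilating arm carries no
    local-relapse node (an assumption of the template, extendable).
    """

    p_sufficient_regression: float
    p_cure_conservative_after_cytoreduction: float
    p_cure_mutilating: float
    p_resectability_lost_on_progression: float
    p_cure_after_interval_progression: float
    u_conservative: float = 1.0
    u_mutilating: float = 0.9
    u_unresectable: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_sufficient_regression",
            "p_cure_conservative_after_cytoreduction",
            "p_cure_mutilating",
            "p_resectability_lost_on_progression",
            "p_cure_after_interval_progression",
            "u_conservative",
            "u_mutilating",
            "u_unresectable",
        ):
            check_probability(getattr(self, name), name)


def cytoreduction_tree(params: CytoreductionParams) -> DecisionTree:
    """Cytoreduction-for-conversion tree (cytoreduction listed first)."""
    insufficient = _chance(
        "interval course without sufficient regression",
        (
            "resectability lost",
            params.p_resectability_lost_on_progression,
            TerminalNode("unresectable disease", params.u_unresectable),
        ),
        (
            "salvage mutilating surgery",
            None,
            _cure_chance(
                "outcome after salvage surgery",
                params.p_cure_after_interval_progression,
                TerminalNode("cure with mutilating surgery", params.u_mutilating),
            ),
        ),
    )
    cyto = _chance(
        "tumor regression under medical therapy",
        (
            "sufficient regression",
            params.p_sufficient_regression,
            _cure_chance(
                "outcome after conservative surgery",
                params.p_cure_conservative_after_cytoreduction,
                TerminalNode("cure with conservative surgery", params.u_conservative),
            ),
        ),
        ("insufficient regression", None, insufficient),
    )
    root = DecisionNode(
        "local treatment strategy",
        [
            DecisionOption("cytoreduction then surgery", cyto),
            DecisionOption(
                "mutilating surgery now",
                _cure_chance(
                    "outcome after mutilating surgery",
                    params.p_cure_mutilating,
                    TerminalNode("cure with mutilating surgery", params.u_mutilating),
                ),
            ),
        ],
    )
    return _finish(root, "utility", "cytoreduction for conversion")


# ---------------------------------------------------------------------------
# Active surveillance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveillanceParams:
    """Immediate treatment vs active surveillance / watchful waiting.

    Under surveillance the disease may or may not evolve; on evolution,
    treatment may no longer be feasible, and delayed treatment may cure
    with a different probability than immediate treatment.  Life under
    surveillance without evolution keeps utility
    ``u_no_treatment_morbidity`` (1 by default: no treatment sequelae);
    cure through treatment — immediate or delayed — carries
    ``u_treatment_sequelae``.
    """

    p_evolution: float
    p_treatment_feasible_at_evolution: float
    p_cure_immediate: float
    p_cure_delayed: float
    u_treatment_sequelae: float
    u_no_treatment_morbidity: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "p_evolution",
            "p_treatment_feasible_at_evolution",
            "p_cure_immediate",
            "p_cure_delayed",
            "u_treatment_sequelae",
            "u_no_treatment_morbidity",
        ):
            check_probability(getattr(self, name), name)


def surveillance_tree(params: SurveillanceParams) -> DecisionTree:
    """Active-surveillance tree (immediate treatment listed first)."""
    delayed = _cure_chance(
        "outcome of delayed treatment",
        params.p_cure_delayed,
        TerminalNode("cure with treatment sequelae", params.u_treatment_sequelae),
    )
    evolution = _chance(
        "treatment feasibility at evolution",
        ("treatment feasible", params.p_treatment_feasible_at_evolution, delayed),
        ("treatment unfeasible", None, TerminalNode("no cure", 0.0)),
    )
    surveillance = _chance(
        "disease course under surveillance",
        ("evolution", params.p_evolution, evolution),
        (
            "no evolution",
            None,
            TerminalNode("no evolution, no treatment", params.u_no_treatment_morbidity),
        ),
    )
    root = DecisionNode(
        "management choice",
        [
            DecisionOption(
                "immediate treatment",
                _cure_chance(
                    "outcome of immediate treatment",
                    params.p_cure_immediate,
                    TerminalNode("cure with treatment sequelae", params.u_treatment_sequelae),
                ),
            ),
            DecisionOption("active surveillance", surveillance),
        ],
    )
    return _finish(root, "utility", "active surveillance")


# ---------------------------------------------------------------------------
# Advanced disease
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdvancedDiseaseOption:
    """One active treatment option, described by clinical-benefit bins.

    ``bins`` are ``(label, probability, value)`` triples — e.g. the
    output of :func:`~oncomda.evidence.discretize_pfs` mapped to
    (label, probability, representative duration) — whose probabilities
    sum to 1.  The dichotomous benefit/no-benefit description is the
    two-bin special case (:meth:`from_benefit`).
    """

    name: str
    bins: Tuple[Tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.bins) < 2:
            raise DomainError(f"option {self.name!r} needs >= 2 outcome bins")
        for label, p, v in self.bins:
            check_probability(p, f"{self.name}/{label} probability")

    @classmethod
    def from_benefit(
        cls,
        name: str,
        p_benefit: float,
        benefit_value: float,
        no_benefit_value: float,
    ) -> "AdvancedDiseaseOption":
        return cls(
            name=name,
            bins=(
                ("clinical benefit", p_benefit, benefit_value),
                ("no clinical benefit", 1.0 - p_benefit, no_benefit_value),
            ),
        )


@dataclass(frozen=True)
class AdvancedDiseaseParams:
    """Treatment options vs best supportive care in advanced disease.

    Terminal values share one declared measure — typically
    ``"life_years"`` (benefit durations, in the declared time unit) or
    ``"qaly"`` (durations already weighted by toxicity utilities via
    :func:`~oncomda.evidence.qaly`).  Best supportive care is always
    present, as "not to treat" is itself a treatment choice.
    """

    options: Tuple[AdvancedDiseaseOption, ...]
    bsc_value: float
    measure: str = "life_years"
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if not self.options:
            raise DomainError("need at least one active treatment option")
        if self.bsc_value < 0:
            raise DomainError("best-supportive-care value must be >= 0")


def advanced_disease_tree(params: AdvancedDiseaseParams) -> DecisionTree:
    """Advanced-disease tree: per-option benefit chance nodes plus BSC.

    Using bins instead of a single median duration keeps the radically
    different experiences of responders and non-responders distinct.
    """
    if params.measure == "utility":
        raise DomainError(
            "advanced-disease terminals carry durations; measure must be "
            "'life_years' or 'qaly'"
        )
    opts: List[DecisionOption] = []
    for opt in params.options:
        branches = [
            ChanceBranch(label, p, TerminalNode(label, value))
            for label, p, value in opt.bins
        ]
        opts.append(
            DecisionOption(opt.name, ChanceNode(f"clinical benefit with {opt.name}", branches))
        )
    opts.append(
        DecisionOption(
            "best supportive care",
            # modelled as a terminal: no benefit/no-benefit split applies
            TerminalNode("best supportive care", params.bsc_value),
        )
    )
    root = DecisionNode("treatment choice in advanced disease", opts)
    return _finish(
        root, params.measure, "advanced disease", time_unit=params.time_unit
    )


# ---------------------------------------------------------------------------
# Follow-up
# ---------------------------------------------------------------------------

def followup_subtree(p_relapse_window: float, test: TestCharacteristics) -> ChanceNode:
    """Four-branch follow-up chance node: relapse risk x test performance.

    Branch probabilities are the TP/FN/FP/TN joint probabilities from
    :func:`~oncomda.evidence.test_outcome_probabilities`; the window
    relapse risk typically comes from
    :func:`~oncomda.evidence.event_probability_in_window`.  Children are
    placeholder terminals (value 0) that the caller grafts real subtrees
    onto when embedding this node in a larger tree.
    """
    probs = test_outcome_probabilities(p_relapse_window, test)
    labels = {
        "TP": "relapse, detected",
        "FN": "relapse, missed",
        "FP": "no relapse, false alarm",
        "TN": "no relapse, reassured",
    }
    return ChanceNode(
        "follow-up visit",
        [
            ChanceBranch(labels[k], probs[k], TerminalNode(labels[k], 0.0))
            for k in ("TP", "FN", "FP", "TN")
        ],
    )
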