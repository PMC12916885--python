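"""Tree evaluation: fold-back, path enumeration, and risk analysis.

Fold-back (rollback) evaluates a tree backwards from its leaves: a chance
node is worth the probability-weighted average of its children, a decision
node is worth the best of its options.  The recommended root option is the
one maximizing expected value; ties are broken in favour of the
first-listed option and reported.

Risk analysis drops utilities entirely: per root option it sums the
probabilities of every root-to-terminal path landing in each outcome
label, giving the probability distribution over final outcomes that the
patient can weigh directly.  On trees with embedded decision nodes the
profile is defined conditional on a policy (by default, the fold-back
optimal one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

from .tree_model import (
    PROB_ATOL,
    ChanceNode,
    DecisionNode,
    DecisionTree,
    DomainError,
    Node,
    PolicyError,
    TerminalNode,
    validate,
)

__all__ = [
    "Policy",
    "EvaluationResult",
    "PathRecord",
    "RiskProfile",
    "fold_back",
    "enumerate_paths",
    "risk_analysis",
]


@dataclass(frozen=True)
class Policy:
    """A resolution of decision nodes: node path -> chosen option label.

    The root decision node has path ``""``.  A well-formed policy contains
    exactly the decision nodes reachable under its own choices.
    """

    choices: Dict[str, str] = field(default_factory=dict)

    def choice_at(self, path: str) -> str:
        try:
            return self.choices[path]
        except KeyError:
            raise PolicyError(f"policy does not cover decision node at {path!r}") from None


@dataclass
class EvaluationResult:
    """Outcome of :func:`fold_back`.

    ``option_values`` maps each root option to its expected value in the
    tree's measure; ``policy`` is the EU-optimal policy restricted to
    decision nodes reachable under it; ``all_choices`` records the optimal
    choice at *every* decision node (reachable or not), which risk analysis
    of non-optimal root options needs; ``node_values`` gives the expected
    value at every node path for reporting; ``ties`` lists decision-node
    paths where two or more options were exactly tied.
    """

    option_values: Dict[str, float]
    optimal_option: str
    policy: Policy
    all_choices: Dict[str, str]
    node_values: Dict[str, float]
    ties: List[str]
    measure: str

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "option_values": self.option_values,
            "optimal_option": self.optimal_option,
            "policy": dict(self.policy.choices),
            "ties": list(self.ties),
        }


@dataclass(frozen=True)
class PathRecord:
    """One root-to-terminal path: its branch labels, probability, terminal."""

    option: str
    path: str
    probability: float
    terminal: TerminalNode


@dataclass
class RiskProfile:
    """Per root option, the probability of each final outcome label.

    Each option's probabilities sum to 1: every path ends somewhere.
    """

    profiles: Dict[str, Dict[str, float]]
    policy: Optional[Policy] = None

    def to_dict(self) -> dict:
        out: dict = {"profiles": {k: dict(v) for k, v in self.profiles.items()}}
        if self.policy is not None:
            out["policy"] = dict(self.policy.choices)
        return out


def _terminal_value(node: TerminalNode, path: str) -> float:
    if node.value is None:
        raise DomainError(
            f"terminal at {path!r} has no value; fold-back needs valued terminals"
        )
    return node.value


def fold_back(tree: DecisionTree) -> EvaluationResult:
    """Evaluate the tree backwards and return expected values and policy.

    Chance-node value = sum of p_i * value(child_i); decision-node value =
    max over options, ties broken by the first-listed option and recorded.
    Raises :class:`~oncomda.tree_model.TreeValidationError` on an invalid
    tree and :class:`~oncomda.tree_model.DomainError` if a terminal lacks
    a value.
    """
    validate(tree).raise_if_invalid()

    node_values: Dict[str, float] = {}
    all_choices: Dict[str, str] = {}
    ties: List[str] = []

    def value(node: Node, path: str) -> float:
        if isinstance(node, TerminalNode):
            v = _terminal_value(node, path)
        elif isinstance(node, ChanceNode):
            v = sum(
                b.p * value(b.child, f"{path}/{b.label}" if path else b.label)
                for b in node.branches
            )
        else:
            child_values = [
                value(o.child, f"{path}/{o.label}" if path else o.label)
                for o in node.options
            ]
            best = max(child_values)
            if sum(1 for cv in child_values if cv == best) > 1:
                ties.append(path)
            idx = child_values.index(best)  # first-listed wins ties
            all_choices[path] = node.options[idx].label
            v = best
        node_values[path] = v
        return v

    value(tree.root, "")

    option_values = {
        o.label: node_values[o.label] for o in tree.root.options
    }
    optimal = all_choices[""]

    # Restrict to decision nodes reachable under the optimal choices.
    reachable: Dict[str, str] = {}

    def walk(node: Node, path: str) -> None:
        if isinstance(node, TerminalNode):
            return
        if isinstance(node, DecisionNode):
            chosen = all_choices[path]
            reachable[path] = chosen
            opt = next(o for o in node.options if o.label == chosen)
            walk(opt.child, f"{path}/{chosen}" if path else chosen)
        else:
            for b in node.branches:
                walk(b.child, f"{path}/{b.label}" if path else b.label)

    walk(tree.root, "")

    return EvaluationResult(
        option_values=option_values,
        optimal_option=optimal,
        policy=Policy(reachable),
        all_choices=all_choices,
        node_values=node_values,
        ties=ties,
        measure=tree.measure,
    )


def enumerate_paths(
    tree_or_node: Union[DecisionTree, Node],
    policy: Optional[Policy] = None,
) -> List[PathRecord]:
    """List every root-to-terminal path with its probability.

    A path's probability is the product of the chance probabilities along
    it.  At the root decision node *all* options are enumerated (each path
    is tagged with its root option); embedded decision nodes are resolved
    by ``policy``.  Per root option, path probabilities sum to 1.

    Accepts a bare node as well as a tree, in which case paths are
    enumerated from that node and tagged with option ``""``.
    """
    policy = policy or Policy({})
    records: List[PathRecord] = []

    def descend(node: Node, option: str, path: str, prob: float) -> None:
        if isinstance(node, TerminalNode):
            records.append(PathRecord(option, path, prob, node))
        elif isinstance(node, ChanceNode):
            for b in node.branches:
                descend(b.child, option, f"{path}/{b.label}" if path else b.label, prob * b.p)
        else:
            chosen = policy.choice_at(path)
            match = [o for o in node.options if o.label == chosen]
            if not match:
                raise PolicyError(
                    f"policy chooses {chosen!r} at {path!r} but no such option exists"
                )
            descend(match[0].child, option, f"{path}/{chosen}" if path else chosen, prob)

    if isinstance(tree_or_node, DecisionTree):
        for o in tree_or_node.root.options:
            descend(o.child, o.label, o.label, 1.0)
    elif isinstance(tree_or_node, DecisionNode):
        for o in tree_or_node.options:
            descend(o.child, o.label, o.label, 1.0)
    else:
        descend(tree_or_node, "", "", 1.0)
    return records


def risk_analysis(tree: DecisionTree, policy: Optional[Policy] = None) -> RiskProfile:
    """Per root option, sum path probabilities into each outcome label.

    If ``policy`` is omitted, the fold-back optimal choices are used; this
    requires terminal values.  A purely probabilistic tree (no terminal
    values) with embedded decision nodes needs an explicit policy.
    """
    validate(tree).raise_if_invalid()

    has_embedded = any(
        isinstance(node, DecisionNode) and path != "" for path, node in _iter(tree)
    )
    if policy is None:
        if has_embedded:
            valued = all(
                node.value is not None
                for _, node in _iter(tree)
                if isinstance(node, TerminalNode)
            )
            if not valued:
                raise PolicyError(
                    "tree has embedded decision nodes but no terminal values; "
                    "risk analysis needs an explicit policy"
                )
            policy = Policy(fold_back(tree).all_choices)
        else:
            policy = Policy({})

    profiles: Dict[str, Dict[str, float]] = {}
    for rec in enumerate_paths(tree, policy):
        row = profiles.setdefault(rec.option, {})
        row[rec.terminal.outcome] = row.get(rec.terminal.outcome, 0.0) + rec.probability

    for option, row in profiles.items():
        total = sum(row.values())
        if abs(total - 1.0) > PROB_ATOL:
            raise DomainError(
                f"risk profile for option {option!r} sums to {total!r}, not 1"
            )
    return RiskProfile(profiles=profiles, policy=policy)


def _iter(tree: DecisionTree):
    from .tree_model import iter_nodes

    return iter_nodes(tree)
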