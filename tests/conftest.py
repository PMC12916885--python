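"""Shared fixtures: canonical small trees and an independent oracle.

The oracle evaluates a tree by exhaustive policy enumeration — for each
root option it tries every possible assignment of choices to embedded
decision nodes and takes the best path-probability-weighted expectation.
It deliberately shares no code with the package's fold-back so the two
routes check each other.
"""

from itertools import product

import pytest

from oncomda.tree_model import (
    ChanceBranch,
    ChanceNode,
    DecisionNode,
    DecisionOption,
    DecisionTree,
    TerminalNode,
)


def _collect_decision_nodes(node):
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if isinstance(n, DecisionNode):
            out.append(n)
            stack.extend(o.child for o in n.options)
        elif isinstance(n, ChanceNode):
            stack.extend(b.child for b in n.branches)
    return out


def _expectation(node, assign):
    if isinstance(node, TerminalNode):
        return node.value
    if isinstance(node, ChanceNode):
        return sum(b.p * _expectation(b.child, assign) for b in node.branches)
    return _expectation(node.options[assign[id(node)]].child, assign)


def oracle_option_values(tree):
    """Per-root-option expected value by brute-force policy enumeration."""
    values = {}
    for opt in tree.root.options:
        decisions = _collect_decision_nodes(opt.child)
        best = None
        for combo in product(*(range(len(d.options)) for d in decisions)):
            assign = {id(d): c for d, c in zip(decisions, combo)}
            v = _expectation(opt.child, assign)
            best = v if best is None else max(best, v)
        values[opt.label] = best
    return values


def embedded_decision_count(tree):
    return sum(len(_collect_decision_nodes(o.child)) for o in tree.root.options)


def make_basic_tree(p_cure_a=0.7, p_cure_b=0.5, u_cure=1.0, u_no_cure=0.0):
    """The canonical two-option cure/no-cure tree (treatment A vs B)."""
    def arm(p):
        return ChanceNode(
            "outcome",
            [
                ChanceBranch("cure", p, TerminalNode("cure", u_cure)),
                ChanceBranch("no cure", None, TerminalNode("no cure", u_no_cure)),
            ],
        )

    root = DecisionNode(
        "treatment choice",
        [
            DecisionOption("treatment A", arm(p_cure_a)),
            DecisionOption("treatment B", arm(p_cure_b)),
        ],
    )
    return DecisionTree(root=root, measure="utility")


@pytest.fixture
def basic_tree():
    return make_basic_tree()
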