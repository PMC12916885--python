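"""Decision-tree data model: nodes, validation, and JSON (de)serialization.

A decision tree is a rooted, acyclic structure of three node kinds:

* :class:`DecisionNode` — the physician chooses among mutually exclusive
  options (drawn as a square);
* :class:`ChanceNode` — nature resolves among mutually exclusive events,
  each carrying a probability; probabilities at a chance node sum to 1
  because the envisaged events must be exhaustive (drawn as a circle);
* :class:`TerminalNode` — a leaf holding a final outcome label and,
  optionally, its value (drawn as a box).

Terminal values are interpreted under a single tree-level *measure*:
``"utility"`` (unitless, in [0, 1]), ``"life_years"``, or ``"qaly"``.
A purely probabilistic tree (for risk analysis only) may leave terminal
values unset.

Nodes inside a tree are addressed by a slash-separated path of branch
labels from the root, e.g. ``"surgery/local relapse/rescue"``; the root
itself has the empty path ``""``.  Paths are stable under
re-serialization and are the addressing scheme used by validation
reports and sensitivity analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple, Union

__all__ = [
    "PROB_ATOL",
    "MEASURES",
    "SCHEMA_VERSION",
    "OncoMdaError",
    "FormatError",
    "DomainError",
    "PolicyError",
    "ParameterError",
    "ExtrapolationError",
    "TreeValidationError",
    "TerminalNode",
    "ChanceBranch",
    "ChanceNode",
    "DecisionOption",
    "DecisionNode",
    "DecisionTree",
    "Node",
    "Violation",
    "ValidationReport",
    "validate",
    "parse_tree",
    "serialize_tree",
    "resolve_path",
    "iter_nodes",
    "check_probability",
]

#: Absolute tolerance on chance-node probability sums.  Elicited values are
#: coarse (often on a 0.05 grid); float noise must never fail validation.
PROB_ATOL = 1e-9

MEASURES = ("utility", "life_years", "qaly")

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OncoMdaError(Exception):
    """Base class for all package errors."""


class FormatError(OncoMdaError):
    """Unparseable or schema-violating input document.

    Carries ``pointer``, a JSON-pointer-like path to the offending element.
    """

    def __init__(self, message: str, pointer: str = ""):
        super().__init__(f"{message} (at {pointer or '/'})")
        self.pointer = pointer


class DomainError(OncoMdaError):
    """A scalar input outside its mathematical domain."""


class PolicyError(OncoMdaError):
    """A policy does not cover a reachable decision node."""


class ParameterError(OncoMdaError):
    """A parameter reference does not resolve to a unique tree location."""


class ExtrapolationError(DomainError):
    """A time outside a survival curve's support; no silent extrapolation."""


class TreeValidationError(OncoMdaError):
    """An operation requiring a valid tree received an invalid one."""

    def __init__(self, report: "ValidationReport"):
        super().__init__("invalid decision tree:\n" + str(report))
        self.report = report


def check_probability(value: float, name: str = "probability") -> float:
    """Check ``0 <= value <= 1`` and return ``value``; raise DomainError otherwise."""
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise DomainError(f"{name} must be a real number, got {value!r}")
    if not (0.0 <= value <= 1.0):
        raise DomainError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# Node types
# ---------------------------------------------------------------------------

@dataclass
class TerminalNode:
    """Leaf node: a final outcome and (optionally) its value.

    ``value`` is interpreted under the owning tree's measure; ``None`` marks
    a purely probabilistic tree, usable for risk analysis but not fold-back.
    """

    outcome: str
    value: Optional[float] = None
    extra: Dict[str, object] = field(default_factory=dict)


@dataclass
class ChanceBranch:
    label: str
    p: Optional[float]
    child: "Node"
    extra: Dict[str, object] = field(default_factory=dict)


@dataclass
class ChanceNode:
    """Event node; branch probabilities must sum to 1.

    A two-branch node may specify only one probability; the complement is
    auto-filled on construction (P(no cure) = 1 - P(cure)).
    """

    label: str
    branches: List[ChanceBranch]
    extra: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fill_complement()

    def fill_complement(self) -> None:
        """Fill the single missing probability of a two-branch node."""
        if len(self.branches) == 2:
            ps = [b.p for b in self.branches]
            if ps.count(None) == 1:
                known = next(p for p in ps if p is not None)
                if 0.0 <= known <= 1.0:
                    for b in self.branches:
                        if b.p is None:
                            b.p = 1.0 - known


@dataclass
class DecisionOption:
    label: str
    child: "Node"
    extra: Dict[str, object] = field(default_factory=dict)


@dataclass
class DecisionNode:
    """Choice node; the physician selects exactly one option."""

    label: str
    options: List[DecisionOption]
    extra: Dict[str, object] = field(default_factory=dict)


Node = Union[DecisionNode, ChanceNode, TerminalNode]


@dataclass
class DecisionTree:
    """A rooted decision tree with a tree-level outcome measure.

    The measure is a tree attribute rather than per-terminal so that
    expected values are always dimensionally coherent.
    """

    root: DecisionNode
    measure: str = "utility"
    metadata: Dict[str, object] = field(default_factory=dict)
    extra: Dict[str, object] = field(default_factory=dict)

    def copy(self) -> "DecisionTree":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Traversal helpers
# ---------------------------------------------------------------------------

def _children(node: Node) -> List[Tuple[str, Node]]:
    if isinstance(node, DecisionNode):
        return [(o.label, o.child) for o in node.options]
    if isinstance(node, ChanceNode):
        return [(b.label, b.child) for b in node.branches]
    return []


def iter_nodes(tree_or_node: Union[DecisionTree, Node]) -> Iterator[Tuple[str, Node]]:
    """Yield ``(path, node)`` pairs in depth-first pre-order.

    Paths are slash-joined branch labels from the root; the root has path "".
    """
    root = tree_or_node.root if isinstance(tree_or_node, DecisionTree) else tree_or_node
    stack: List[Tuple[str, Node]] = [("", root)]
    while stack:
        path, node = stack.pop()
        yield path, node
        for label, child in reversed(_children(node)):
            stack.append((f"{path}/{label}" if path else label, child))


def resolve_path(tree_or_node: Union[DecisionTree, Node], path: str) -> Node:
    """Return the node addressed by a slash-separated branch-label path.

    Raises :class:`ParameterError` if any segment does not match a branch
    or option label.
    """
    node = tree_or_node.root if isinstance(tree_or_node, DecisionTree) else tree_or_node
    if path == "":
        return node
    walked: List[str] = []
    for segment in path.split("/"):
        match = [child for label, child in _children(node) if label == segment]
        if len(match) != 1:
            where = "/".join(walked) or "<root>"
            raise ParameterError(
                f"path segment {segment!r} does not resolve uniquely under {where!r}"
            )
        node = match[0]
        walked.append(segment)
    return node


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    path: str
    message: str

    def __str__(self) -> str:
        return f"[{self.path or '<root>'}] {self.message}"


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: a list of violations, empty if valid."""

    violations: List[Violation] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.is_valid:
            return "valid"
        return "\n".join(str(v) for v in self.violations)

    def raise_if_invalid(self) -> None:
        if not self.is_valid:
            raise TreeValidationError(self)


def validate(tree: DecisionTree) -> ValidationReport:
    """Check every structural invariant; violations are data, not exceptions.

    Checks: root is a decision node; decision nodes have >= 2 uniquely
    labelled options; chance nodes have >= 2 uniquely labelled branches with
    probabilities in [0, 1] summing to 1 within ``PROB_ATOL``; terminal
    outcome labels are non-empty; utility values lie in [0, 1]; the measure
    is known; the structure is a tree (no shared nodes, no cycles).
    """
    report = ValidationReport()
    add = report.violations.append

    if tree.measure not in MEASURES:
        add(Violation("", f"unknown measure {tree.measure!r}; expected one of {MEASURES}"))

    if not isinstance(tree.root, DecisionNode):
        add(Violation("", "root must be a decision node"))
        return report

    seen_ids: set[int] = set()
    for path, node in iter_nodes(tree):
        if id(node) in seen_ids:
            add(Violation(path, "node appears more than once (tree must be acyclic)"))
            continue
        seen_ids.add(id(node))

        if isinstance(node, DecisionNode):
            if len(node.options) < 2:
                add(Violation(path, f"decision node has {len(node.options)} option(s); needs >= 2"))
            labels = [o.label for o in node.options]
            if len(set(labels)) != len(labels):
                add(Violation(path, "option labels must be unique within the node"))
        elif isinstance(node, ChanceNode):
            if len(node.branches) < 2:
                add(Violation(path, f"chance node has {len(node.branches)} branch(es); needs >= 2"))
            labels = [b.label for b in node.branches]
            if len(set(labels)) != len(labels):
                add(Violation(path, "event labels must be unique within the node"))
            missing = [b.label for b in node.branches if b.p is None]
            if missing:
                add(Violation(path, f"branch probability missing for {missing!r}"))
            else:
                for b in node.branches:
                    if not (0.0 <= b.p <= 1.0):  # type: ignore[operator]
                        add(Violation(path, f"branch {b.label!r} probability {b.p} outside [0, 1]"))
                total = sum(b.p for b in node.branches)  # type: ignore[misc]
                if abs(total - 1.0) > PROB_ATOL:
                    add(Violation(path, f"branch probabilities sum to {total!r}, not 1"))
        elif isinstance(node, TerminalNode):
            if not node.outcome:
                add(Violation(path, "terminal outcome label must be non-empty"))
            if node.value is not None and tree.measure == "utility":
                if not (0.0 <= node.value <= 1.0):
                    add(Violation(path, f"utility {node.value} outside [0, 1]"))
            if node.value is not None and tree.measure in ("life_years", "qaly"):
                if node.value < 0:
                    add(Violation(path, f"{tree.measure} value {node.value} is negative"))
        else:
            add(Violation(path, f"unknown node object {type(node).__name__}"))
    return report


# ---------------------------------------------------------------------------
# JSON (de)serialization
# ---------------------------------------------------------------------------
#
# Schema (informal), version "1":
#   {"schema_version": "1", "measure": "utility"|"life_years"|"qaly",
#    "metadata": {...}, "root": <node>}
#   <node> := {"kind": "decision", "label": str, "options":
#                 [{"label": str, "child": <node>}]}
#           | {"kind": "chance", "label": str, "branches":
#                 [{"label": str, "p": number|null, "child": <node>}]}
#           | {"kind": "terminal", "outcome": str, "value": number|null}
# Unknown keys anywhere are preserved (forward compatibility), never dropped.

_NODE_KEYS = {
    "decision": {"kind", "label", "options"},
    "chance": {"kind", "label", "branches"},
    "terminal": {"kind", "outcome", "value"},
}


def _require(obj: dict, key: str, pointer: str) -> object:
    if key not in obj:
        raise FormatError(f"missing required key {key!r}", pointer)
    return obj[key]


def _parse_node(obj: object, pointer: str) -> Node:
    if not isinstance(obj, dict):
        raise FormatError("node must be a JSON object", pointer)
    kind = _require(obj, "kind", pointer)
    if kind not in _NODE_KEYS:
        raise FormatError(f"unknown node kind {kind!r}", f"{pointer}/kind")
    extra = {k: v for k, v in obj.items() if k not in _NODE_KEYS[kind]}

    if kind == "terminal":
        outcome = _require(obj, "outcome", pointer)
        if not isinstance(outcome, str):
            raise FormatError("terminal outcome must be a string", f"{pointer}/outcome")
        value = obj.get("value")
        if value is not None and not isinstance(value, (int, float)):
            raise FormatError("terminal value must be a number or null", f"{pointer}/value")
        return TerminalNode(outcome=outcome, value=None if value is None else float(value), extra=extra)

    label = _require(obj, "label", pointer)
    if not isinstance(label, str):
        raise FormatError("node label must be a string", f"{pointer}/label")

    if kind == "decision":
        options = _require(obj, "options", pointer)
        if not isinstance(options, list):
            raise FormatError("options must be a list", f"{pointer}/options")
        parsed_opts = []
        for i, opt in enumerate(options):
            p = f"{pointer}/options/{i}"
            if not isinstance(opt, dict):
                raise FormatError("option must be a JSON object", p)
            olabel = _require(opt, "label", p)
            child = _parse_node(_require(opt, "child", p), f"{p}/child")
            oextra = {k: v for k, v in opt.items() if k not in {"label", "child"}}
            parsed_opts.append(DecisionOption(label=olabel, child=child, extra=oextra))
        return DecisionNode(label=label, options=parsed_opts, extra=extra)

    branches = _require(obj, "branches", pointer)
    if not isinstance(branches, list):
        raise FormatError("branches must be a list", f"{pointer}/branches")
    parsed_brs = []
    n_missing = 0
    for i, br in enumerate(branches):
        p = f"{pointer}/branches/{i}"
        if not isinstance(br, dict):
            raise FormatError("branch must be a JSON object", p)
        blabel = _require(br, "label", p)
        prob = br.get("p")
        if prob is None:
            n_missing += 1
        elif not isinstance(prob, (int, float)) or isinstance(prob, bool):
            raise FormatError("branch probability must be a number or null", f"{p}/p")
        child = _parse_node(_require(br, "child", p), f"{p}/child")
        bextra = {k: v for k, v in br.items() if k not in {"label", "p", "child"}}
        parsed_brs.append(ChanceBranch(label=blabel, p=None if prob is None else float(prob), child=child, extra=bextra))
    # Only a two-branch node may omit a probability (complement auto-fill).
    if n_missing > 0 and not (len(parsed_brs) == 2 and n_missing == 1):
        raise FormatError(
            "a branch probability may be omitted only on a two-branch node, and only once",
            f"{pointer}/branches",
        )
    return ChanceNode(label=label, branches=parsed_brs, extra=extra)


def parse_tree(document: str) -> DecisionTree:
    """Parse a tree JSON document into a :class:`DecisionTree`.

    Unknown keys are accepted and preserved so that documents written by a
    newer schema round-trip unchanged.  Schema violations raise
    :class:`FormatError` with a JSON-pointer-style location.
    """
    try:
        obj = json.loads(document)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}", "") from exc
    if not isinstance(obj, dict):
        raise FormatError("top-level document must be a JSON object", "")

    measure = obj.get("measure", "utility")
    if measure not in MEASURES:
        raise FormatError(f"measure must be one of {MEASURES}", "/measure")
    metadata = obj.get("metadata", {})
    if not isinstance(metadata, dict):
        raise FormatError("metadata must be a JSON object", "/metadata")

    root = _parse_node(_require(obj, "root", ""), "/root")
    if not isinstance(root, DecisionNode):
        raise FormatError("root must be a decision node", "/root")

    known = {"schema_version", "measure", "metadata", "root"}
    extra = {k: v for k, v in obj.items() if k not in known}
    return DecisionTree(root=root, measure=measure, metadata=dict(metadata), extra=extra)


def _node_to_obj(node: Node) -> dict:
    if isinstance(node, TerminalNode):
        out = {"kind": "terminal", "outcome": node.outcome, "value": node.value}
    elif isinstance(node, DecisionNode):
        out = {
            "kind": "decision",
            "label": node.label,
            "options": [
                {"label": o.label, "child": _node_to_obj(o.child), **o.extra}
                for o in node.options
            ],
        }
    else:
        out = {
            "kind": "chance",
            "label": node.label,
            "branches": [
                {"label": b.label, "p": b.p, "child": _node_to_obj(b.child), **b.extra}
                for b in node.branches
            ],
        }
    out.update(node.extra)
    return out


def serialize_tree(tree: DecisionTree) -> str:
    """Serialize a valid tree to its JSON document.

    An invalid tree is refused with a :class:`TreeValidationError` carrying
    the full validation report; ``parse_tree(serialize_tree(t))``
    structurally equals ``t``.
    """
    validate(tree).raise_if_invalid()
    obj = {
        "schema_version": SCHEMA_VERSION,
        "measure": tree.measure,
        "metadata": tree.metadata,
        **tree.extra,
        "root": _node_to_obj(tree.root),
    }
    return json.dumps(obj, indent=2, ensure_ascii=False)
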