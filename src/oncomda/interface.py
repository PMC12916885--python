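"""Fixtures, DOT export, and plain-text reporting.

The fixture generators make the whole package testable without any
external dataset: random valid decision trees (probabilities drawn on
the 0.05 elicitation lattice, then renormalized) and synthetic survival
step curves with an optional plateau tail, both fully reproducible from
their spec and seed.

DOT export follows the field's drawing conventions — squares for
decision nodes, circles for chance nodes, boxes for terminals — and is
deterministic, so identical trees always render identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Union

import numpy as np

from .evaluation import EvaluationResult, RiskProfile
from .evidence import SurvivalCurve
from .sensitivity import MonteCarloResult, OneWayResult, TwoWayResult
from .tree_model import (
    ChanceBranch,
    ChanceNode,
    DecisionNode,
    DecisionOption,
    DecisionTree,
    DomainError,
    Node,
    TerminalNode,
    validate,
)

__all__ = [
    "FixtureSpec",
    "generate_random_tree",
    "generate_survival_fixture",
    "to_dot",
    "render_report",
    "plot_one_way",
    "plot_two_way",
    "plot_monte_carlo",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a random fixture tree.

    ``granularity`` is the lattice step for raw probability draws (0.05,
    the realistic elicitation coarseness); ``p_decision`` is the chance
    that an internal node is an embedded decision rather than a chance
    node.
    """

    depth: int = 4
    branching: int = 3
    granularity: float = 0.05
    seed: int = 0
    p_decision: float = 0.15

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise DomainError("depth must be >= 1")
        if self.branching < 2:
            raise DomainError("branching must be >= 2")
        if not (0 < self.granularity <= 0.5):
            raise DomainError("granularity must lie in (0, 0.5]")


def _lattice_probs(rng: np.random.Generator, k: int, step: float) -> List[float]:
    # draw on the elicitation lattice, then renormalize to sum exactly 1
    raw = rng.integers(1, int(round(1.0 / step)), size=k) * step
    total = float(raw.sum())
    return [float(v) / total for v in raw]


def generate_random_tree(spec: FixtureSpec) -> DecisionTree:
    """A random valid decision tree, deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    counter = {"n": 0}

    def fresh(prefix: str) -> str:
        counter["n"] += 1
        return f"{prefix} {counter['n']}"

    def subtree(depth: int) -> Node:
        if depth <= 0 or rng.random() < 0.25:
            return TerminalNode(fresh("outcome"), float(rng.integers(0, 21)) / 20.0)
        k = int(rng.integers(2, spec.branching + 1))
        if rng.random() < spec.p_decision:
            return DecisionNode(
                fresh("choice"),
                [DecisionOption(fresh("option"), subtree(depth - 1)) for _ in range(k)],
            )
        probs = _lattice_probs(rng, k, spec.granularity)
        return ChanceNode(
            fresh("event"),
            [ChanceBranch(fresh("branch"), p, subtree(depth - 1)) for p in probs],
        )

    k = int(rng.integers(2, spec.branching + 1))
    root = DecisionNode(
        "root choice",
        [DecisionOption(fresh("option"), subtree(spec.depth - 1)) for _ in range(k)],
    )
    tree = DecisionTree(root=root, metadata={"fixture_seed": spec.seed})
    validate(tree).raise_if_invalid()
    return tree


def generate_survival_fixture(
    n_steps: int = 8,
    t_max: float = 60.0,
    plateau: Optional[float] = None,
    time_unit: str = "months",
    seed: int = 0,
) -> SurvivalCurve:
    """A synthetic survival step curve, optionally flattening to a plateau.

    Drop sizes are drawn jointly (Dirichlet) so the curve falls from 1 at
    time 0 exactly to ``plateau`` (or a random positive tail) at
    ``t_max``; step times are sorted uniform draws.  Deterministic given
    the seed.
    """
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    tail = plateau if plateau is not None else float(rng.uniform(0.05, 0.5))
    if not (0.0 <= tail < 1.0):
        raise DomainError("plateau must lie in [0, 1)")
    times = np.sort(rng.uniform(0.0, t_max, size=n_steps))
    times[-1] = t_max
    drops = rng.dirichlet(np.ones(n_steps)) * (1.0 - tail)
    survival = 1.0 - np.cumsum(drops)
    survival[-1] = tail
    return SurvivalCurve(times=times, survival=survival, time_unit=time_unit)


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(tree: DecisionTree) -> str:
    """Graphviz DOT text for a valid tree; identical trees render identically.

    Decision nodes are squares, chance nodes circles, terminals boxes;
    edges carry option labels or event labels with their probabilities.
    """
    validate(tree).raise_if_invalid()
    lines = ["digraph decision_tree {", "  rankdir=LR;"]
    edges: List[str] = []
    counter = {"n": 0}

    def emit(node: Node) -> str:
        name = f"n{counter['n']}"
        counter["n"] += 1
        if isinstance(node, DecisionNode):
            lines.append(f'  {name} [shape=square, label="{_dot_escape(node.label)}"];')
            for o in node.options:
                child = emit(o.child)
                edges.append(f'  {name} -> {child} [label="{_dot_escape(o.label)}"];')
        elif isinstance(node, ChanceNode):
            lines.append(f'  {name} [shape=circle, label="{_dot_escape(node.label)}"];')
            for b in node.branches:
                child = emit(b.child)
                edges.append(
                    f'  {name} -> {child} [label="{_dot_escape(b.label)} (p={b.p:.3f})"];'
                )
        else:
            value = "" if node.value is None else f"\\n{node.value:g}"
            lines.append(f'  {name} [shape=box, label="{_dot_escape(node.outcome)}{value}"];')
        return name

    emit(tree.root)
    return "\n".join(lines + edges + ["}"]) + "\n"


# ---------------------------------------------------------------------------
# Plain-text reports
# ---------------------------------------------------------------------------

def _table(rows: List[List[str]], header: List[str]) -> str:
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    out = [fmt.format(*header), fmt.format(*("-" * w for w in widths))]
    out += [fmt.format(*r) for r in rows]
    return "\n".join(out)


def render_report(
    result: Union[EvaluationResult, RiskProfile, MonteCarloResult]
) -> str:
    """Aligned text table for a result (probabilities to 3 decimals, EU to 4)."""
    if isinstance(result, EvaluationResult):
        rows = [
            [opt, f"{v:.4f}", "<- best" if opt == result.optimal_option else ""]
            for opt, v in result.option_values.items()
        ]
        text = _table(rows, ["option", f"expected {result.measure}", ""])
        if result.ties:
            text += "\n\nnote: exact ties at decision node(s) " + ", ".join(
                repr(p or "<root>") for p in result.ties
            ) + "; first-listed option chosen."
        return text

    if isinstance(result, RiskProfile):
        rows = []
        for opt, profile in result.profiles.items():
            for outcome, p in profile.items():
                rows.append([opt, outcome, f"{p:.3f}"])
        text = _table(rows, ["option", "outcome", "probability"])
        if result.policy is not None and result.policy.choices:
            text += "\n\npolicy: " + ", ".join(
                f"{path or '<root>'} -> {choice}"
                for path, choice in sorted(result.policy.choices.items())
            )
        return text

    if isinstance(result, MonteCarloResult):
        rows = [
            [
                opt,
                f"{result.win_proportions[opt]:.3f}",
                f"{result.eu_summary[opt]['mean']:.4f}",
                f"[{result.eu_summary[opt]['q2.5']:.4f}, {result.eu_summary[opt]['q97.5']:.4f}]",
            ]
            for opt in result.win_proportions
        ]
        text = _table(rows, ["option", "win proportion", "mean EU", "95% interval"])
        text += f"\n\ndraws: {result.n}, seed: {result.seed}"
        return text

    raise DomainError(f"cannot render {type(result).__name__}")


# ---------------------------------------------------------------------------
# Plot hooks (matplotlib is imported lazily; not a hard dependency)
# ---------------------------------------------------------------------------

def plot_one_way(result: OneWayResult, ax=None):
    """EU-vs-parameter lines with threshold markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for option, values in result.option_values.items():
        ax.plot(result.grid, values, label=option)
    for thr in result.thresholds:
        for v in thr.values:
            ax.axvline(v, linestyle="--", linewidth=0.8, color="grey")
    ax.set_xlabel(result.param.describe())
    ax.set_ylabel("expected value")
    ax.legend()
    return ax


def plot_two_way(result: TwoWayResult, ax=None):
    """Best-option heat grid over two parameters."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    options = sorted({w for row in result.winners for w in row})
    index: Dict[str, int] = {o: i for i, o in enumerate(options)}
    grid = np.array([[index[w] for w in row] for row in result.winners])
    im = ax.imshow(
        grid,
        origin="lower",
        aspect="auto",
        extent=(result.grid2[0], result.grid2[-1], result.grid1[0], result.grid1[-1]),
    )
    ax.set_xlabel(result.param2.describe())
    ax.set_ylabel(result.param1.describe())
    cbar = ax.figure.colorbar(im, ax=ax, ticks=list(range(len(options))))
    cbar.ax.set_yticklabels(options)
    return ax


def plot_monte_carlo(result: MonteCarloResult, ax=None):
    """Win-proportion bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    options = list(result.win_proportions)
    ax.bar(options, [result.win_proportions[o] for o in options])
    ax.set_ylabel("win proportion")
    ax.set_ylim(0, 1)
    return ax
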