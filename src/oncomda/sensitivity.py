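"""Sensitivity analysis: one-way, two-way, threshold, and Monte Carlo.

Probabilities and utilities carry uncertainty; sensitivity analysis shows
how robust the recommended option is to that uncertainty.

* :func:`one_way` sweeps a single parameter over a grid and tracks each
  root option's expected value (the expected value of any option is
  affine in any single chance probability, so lines on the resulting
  plot are straight).
* :func:`threshold` finds the parameter value(s) at which two options
  have equal expected value — the tipping point of the decision.
* :func:`two_way` maps the best option over a grid of two parameters.
* :func:`monte_carlo` replaces point values with probability
  distributions, refolds the tree for thousands of random draws, and
  reports the proportion of draws each option wins: a 70% win proportion
  means one can be confident at a level of 70% about that option.

Parameters are addressed by :class:`ParameterRef`: the slash-joined
branch-label path of a node plus, for chance probabilities, the branch
label.  When a two-branch probability is set, its complement moves with
it; on wider nodes the remaining branches are rescaled proportionally so
the node keeps summing to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .evaluation import fold_back
from .tree_model import (
    ChanceNode,
    DecisionTree,
    DomainError,
    ParameterError,
    TerminalNode,
    resolve_path,
)

__all__ = [
    "ParameterRef",
    "Point",
    "Uniform",
    "Beta",
    "Distribution",
    "UncertaintySpec",
    "OneWayResult",
    "ThresholdResult",
    "TwoWayResult",
    "MonteCarloResult",
    "set_parameter",
    "one_way",
    "threshold",
    "two_way",
    "monte_carlo",
]

#: Bisection stops when |EU_a - EU_b| falls below this.
BISECTION_TOL = 1e-10
BISECTION_MAX_ITER = 200

#: Default one-way grid: 101 equally spaced admissible points.
DEFAULT_GRID_POINTS = 101

DEFAULT_MC_DRAWS = 10_000


@dataclass(frozen=True)
class ParameterRef:
    """Address of one tunable number in a tree.

    ``path`` is the slash-joined branch-label path of the target node.
    With ``branch`` set, the reference is that branch's probability on a
    chance node; with ``branch=None`` it is the value of a terminal node.
    """

    path: str
    branch: Optional[str] = None

    def describe(self) -> str:
        if self.branch is None:
            return f"value@{self.path or '<root>'}"
        return f"p[{self.branch}]@{self.path or '<root>'}"


def set_parameter(tree: DecisionTree, ref: ParameterRef, value: float) -> None:
    """Set a parameter in place, keeping the tree coherent.

    Chance probabilities: the named branch is set to ``value``; on a
    two-branch node the sibling takes the complement, on wider nodes the
    remaining branches are rescaled proportionally to sum to
    ``1 - value``.  Terminal values: assigned directly (range-checked
    against the tree's measure).
    """
    node = resolve_path(tree, ref.path)
    if ref.branch is None:
        if not isinstance(node, TerminalNode):
            raise ParameterError(f"{ref.describe()}: node at {ref.path!r} is not a terminal")
        if tree.measure == "utility" and not (0.0 <= value <= 1.0):
            raise DomainError(f"{ref.describe()}: utility {value} outside [0, 1]")
        if tree.measure in ("life_years", "qaly") and value < 0:
            raise DomainError(f"{ref.describe()}: {tree.measure} value {value} is negative")
        node.value = float(value)
        return

    if not isinstance(node, ChanceNode):
        raise ParameterError(f"{ref.describe()}: node at {ref.path!r} is not a chance node")
    target = [b for b in node.branches if b.label == ref.branch]
    if len(target) != 1:
        raise ParameterError(f"{ref.describe()}: no unique branch {ref.branch!r} at {ref.path!r}")
    if not (0.0 <= value <= 1.0):
        raise DomainError(
            f"setting p[{ref.branch}]={value} at node {ref.path or '<root>'!r} "
            "would leave a probability outside [0, 1]"
        )
    others = [b for b in node.branches if b.label != ref.branch]
    target[0].p = float(value)
    remainder = 1.0 - value
    rest = sum(b.p for b in others)
    if rest > 0:
        for b in others:
            b.p = b.p * remainder / rest
    else:
        for b in others:
            b.p = remainder / len(others)


def _eu_with(tree: DecisionTree, assignments: Sequence[Tuple[ParameterRef, float]]):
    work = tree.copy()
    for ref, v in assignments:
        set_parameter(work, ref, v)
    return fold_back(work)


def _default_grid(tree: DecisionTree, ref: ParameterRef) -> List[float]:
    node = resolve_path(tree, ref.path)
    if ref.branch is None and isinstance(node, TerminalNode) and tree.measure != "utility":
        raise DomainError(
            f"{ref.describe()}: no default grid for a {tree.measure} terminal value; "
            "pass an explicit grid"
        )
    return list(np.linspace(0.0, 1.0, DEFAULT_GRID_POINTS))


# ---------------------------------------------------------------------------
# One-way and threshold
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    """Crossing value(s) of a parameter where two options have equal EU."""

    param: ParameterRef
    option_a: str
    option_b: str
    values: List[float]

    @property
    def found(self) -> bool:
        return bool(self.values)

    def to_dict(self) -> dict:
        return {
            "parameter": self.param.describe(),
            "option_a": self.option_a,
            "option_b": self.option_b,
            "thresholds": list(self.values),
            "found": self.found,
        }


@dataclass
class OneWayResult:
    """Per-option EU along a parameter grid, plus decision thresholds."""

    param: ParameterRef
    grid: List[float]
    option_values: Dict[str, List[float]]
    winners: List[str]
    thresholds: List[ThresholdResult]

    def to_dict(self) -> dict:
        return {
            "parameter": self.param.describe(),
            "grid": list(self.grid),
            "option_values": {k: list(v) for k, v in self.option_values.items()},
            "winners": list(self.winners),
            "thresholds": [t.to_dict() for t in self.thresholds],
        }


def _bisect(f, lo: float, hi: float) -> float:
    """Bisect an EU difference with a sign change on [lo, hi]."""
    flo = f(lo)
    if abs(flo) <= BISECTION_TOL:
        return lo
    fhi = f(hi)
    if abs(fhi) <= BISECTION_TOL:
        return hi
    for _ in range(BISECTION_MAX_ITER):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= BISECTION_TOL or (hi - lo) < 1e-15:
            return mid
        if (fm > 0) == (flo > 0):
            lo, flo = mid, fm
        else:
            hi, fhi = mid, fm
    return 0.5 * (lo + hi)


def threshold(
    tree: DecisionTree,
    param: ParameterRef,
    option_a: str,
    option_b: str,
    interval: Optional[Tuple[float, float]] = None,
    n_scan: int = DEFAULT_GRID_POINTS,
) -> ThresholdResult:
    """Parameter value(s) where options a and b have equal expected value.

    The admissible interval (default [0, 1]) is scanned on a coarse grid;
    every sign-change bracket of the EU difference is refined by
    bisection to |EU_a - EU_b| <= 1e-10.  No sign change is a legitimate
    no-threshold result (one option dominates), not an error.
    """
    lo, hi = interval if interval is not None else (0.0, 1.0)
    if not (lo < hi):
        raise DomainError(f"threshold interval must be non-degenerate, got [{lo}, {hi}]")

    def diff(x: float) -> float:
        res = _eu_with(tree, [(param, x)])
        for opt in (option_a, option_b):
            if opt not in res.option_values:
                raise ParameterError(f"no root option named {opt!r}")
        return res.option_values[option_a] - res.option_values[option_b]

    xs = np.linspace(lo, hi, n_scan)
    fs = [diff(float(x)) for x in xs]
    roots: List[float] = []
    for i in range(len(xs) - 1):
        a, b = float(xs[i]), float(xs[i + 1])
        fa, fb = fs[i], fs[i + 1]
        if abs(fa) <= BISECTION_TOL:
            roots.append(a)
        elif (fa > 0) != (fb > 0) or abs(fb) <= BISECTION_TOL:
            roots.append(_bisect(diff, a, b))
    if fs and abs(fs[-1]) <= BISECTION_TOL and (not roots or not math.isclose(roots[-1], float(xs[-1]), abs_tol=1e-9)):
        roots.append(float(xs[-1]))
    # De-duplicate near-identical roots from adjacent brackets.
    dedup: List[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-8:
            dedup.append(r)
    return ThresholdResult(param=param, option_a=option_a, option_b=option_b, values=dedup)


def one_way(
    tree: DecisionTree,
    param: ParameterRef,
    grid: Optional[Sequence[float]] = None,
) -> OneWayResult:
    """Sweep one parameter; per grid value, set it and fold back the tree.

    Crossing thresholds are located wherever the winning option changes
    between adjacent grid points and refined by :func:`threshold` on that
    bracket.
    """
    gvals = [float(g) for g in (grid if grid is not None else _default_grid(tree, param))]
    options = [o.label for o in tree.root.options]
    values: Dict[str, List[float]] = {o: [] for o in options}
    winners: List[str] = []
    for g in gvals:
        res = _eu_with(tree, [(param, g)])
        for o in options:
            values[o].append(res.option_values[o])
        winners.append(res.optimal_option)

    thresholds: List[ThresholdResult] = []
    for i in range(len(gvals) - 1):
        if winners[i] != winners[i + 1]:
            thresholds.append(
                threshold(
                    tree,
                    param,
                    winners[i],
                    winners[i + 1],
                    interval=(gvals[i], gvals[i + 1]),
                    n_scan=2,
                )
            )
    return OneWayResult(
        param=param, grid=gvals, option_values=values, winners=winners, thresholds=thresholds
    )


# ---------------------------------------------------------------------------
# Two-way
# ---------------------------------------------------------------------------

@dataclass
class TwoWayResult:
    """Best-option label over a two-parameter grid (rows: param1 grid)."""

    param1: ParameterRef
    param2: ParameterRef
    grid1: List[float]
    grid2: List[float]
    winners: List[List[str]]

    def to_dict(self) -> dict:
        return {
            "parameter1": self.param1.describe(),
            "parameter2": self.param2.describe(),
            "grid1": list(self.grid1),
            "grid2": list(self.grid2),
            "winners": [list(row) for row in self.winners],
        }


def two_way(
    tree: DecisionTree,
    param1: ParameterRef,
    param2: ParameterRef,
    grid1: Sequence[float],
    grid2: Sequence[float],
) -> TwoWayResult:
    """Best option after jointly setting two parameters, over a grid.

    Entry (i, j) is the fold-back winner with ``param1 = grid1[i]`` and
    ``param2 = grid2[j]``; ties break as in fold-back (first listed).
    """
    g1 = [float(g) for g in grid1]
    g2 = [float(g) for g in grid2]
    winners: List[List[str]] = []
    for a in g1:
        row = []
        for b in g2:
            row.append(_eu_with(tree, [(param1, a), (param2, b)]).optimal_option)
        winners.append(row)
    return TwoWayResult(param1=param1, param2=param2, grid1=g1, grid2=g2, winners=winners)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Point:
    value: float


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float


@dataclass(frozen=True)
class Beta:
    alpha: float
    beta: float


Distribution = Union[Point, Uniform, Beta]


def _sample(dist: Distribution, rng: np.random.Generator) -> float:
    if isinstance(dist, Point):
        return dist.value
    if isinstance(dist, Uniform):
        return float(rng.uniform(dist.lo, dist.hi))
    if isinstance(dist, Beta):
        return float(rng.beta(dist.alpha, dist.beta))
    raise ParameterError(f"unknown distribution {dist!r}")


@dataclass
class UncertaintySpec:
    """Distributions over tree parameters for Monte-Carlo sensitivity.

    Three kinds of entries:

    * a single chance-branch probability with a point / uniform / beta
      distribution (its complement, or the proportional rescale of the
      remaining branches, keeps the node coherent);
    * a whole chance node sampled jointly from a Dirichlet — required
      when more than two branches of one node are uncertain, so the node
      always sums to 1 without biasing any branch;
    * a terminal value with a point / uniform / beta distribution
      (supports must respect the tree's measure domain).

    Optional orderings ``(lower_terminal_path, upper_terminal_path)``
    constrain sampled terminal values (e.g. cure-with-sequelae <= cure)
    by rejection sampling; none are assumed by default.
    """

    probabilities: List[Tuple[ParameterRef, Distribution]] = field(default_factory=list)
    dirichlet_nodes: List[Tuple[str, Tuple[float, ...]]] = field(default_factory=list)
    values: List[Tuple[ParameterRef, Distribution]] = field(default_factory=list)
    orderings: List[Tuple[str, str]] = field(default_factory=list)

    def add_probability(self, path: str, branch: str, dist: Distribution) -> "UncertaintySpec":
        self.probabilities.append((ParameterRef(path, branch), dist))
        return self

    def add_dirichlet(self, path: str, alphas: Sequence[float]) -> "UncertaintySpec":
        self.dirichlet_nodes.append((path, tuple(float(a) for a in alphas)))
        return self

    def add_value(self, path: str, dist: Distribution) -> "UncertaintySpec":
        self.values.append((ParameterRef(path, None), dist))
        return self

    def add_ordering(self, lower_path: str, upper_path: str) -> "UncertaintySpec":
        self.orderings.append((lower_path, upper_path))
        return self

    # -- JSON interchange (used by the CLI) -----------------------------
    @classmethod
    def from_dict(cls, obj: dict) -> "UncertaintySpec":
        spec = cls()
        for entry in obj.get("parameters", []):
            d = entry.get("dist", {})
            kind = d.get("type")
            if kind == "point":
                dist: Distribution = Point(float(d["value"]))
            elif kind == "uniform":
                dist = Uniform(float(d["lo"]), float(d["hi"]))
            elif kind == "beta":
                dist = Beta(float(d["alpha"]), float(d["beta"]))
            elif kind == "dirichlet":
                spec.add_dirichlet(entry["path"], [float(a) for a in d["alphas"]])
                continue
            else:
                raise ParameterError(f"unknown distribution type {kind!r}")
            if entry.get("branch") is not None:
                spec.add_probability(entry["path"], entry["branch"], dist)
            else:
                spec.add_value(entry["path"], dist)
        for pair in obj.get("orderings", []):
            spec.add_ordering(pair[0], pair[1])
        return spec

    def validate_against(self, tree: DecisionTree) -> None:
        """Resolve every reference and enforce coherence rules."""
        per_node: Dict[str, int] = {}
        for ref, dist in self.probabilities:
            node = resolve_path(tree, ref.path)
            if not isinstance(node, ChanceNode):
                raise ParameterError(f"{ref.describe()}: not a chance node")
            if ref.branch not in [b.label for b in node.branches]:
                raise ParameterError(f"{ref.describe()}: no such branch")
            per_node[ref.path] = per_node.get(ref.path, 0) + 1
            _check_prob_support(dist, ref)
        for path, count in per_node.items():
            node = resolve_path(tree, path)
            if len(node.branches) > 2 and count > 1:  # type: ignore[union-attr]
                raise ParameterError(
                    f"chance node {path!r} has >2 uncertain branches; "
                    "use a joint dirichlet over the whole node"
                )
        for path, alphas in self.dirichlet_nodes:
            node = resolve_path(tree, path)
            if not isinstance(node, ChanceNode):
                raise ParameterError(f"dirichlet@{path!r}: not a chance node")
            if len(alphas) != len(node.branches):
                raise ParameterError(
                    f"dirichlet@{path!r}: {len(alphas)} alphas for "
                    f"{len(node.branches)} branches"
                )
            if any(a <= 0 for a in alphas):
                raise ParameterError(f"dirichlet@{path!r}: alphas must be positive")
            if path in per_node:
                raise ParameterError(
                    f"chance node {path!r} has both per-branch and dirichlet entries"
                )
        for ref, dist in self.values:
            node = resolve_path(tree, ref.path)
            if not isinstance(node, TerminalNode):
                raise ParameterError(f"{ref.describe()}: not a terminal node")
            if tree.measure == "utility":
                _check_prob_support(dist, ref)
        for low, high in self.orderings:
            for p in (low, high):
                if not isinstance(resolve_path(tree, p), TerminalNode):
                    raise ParameterError(f"ordering endpoint {p!r} is not a terminal")


def _check_prob_support(dist: Distribution, ref: ParameterRef) -> None:
    if isinstance(dist, Point) and not (0.0 <= dist.value <= 1.0):
        raise ParameterError(f"{ref.describe()}: point mass {dist.value} outside [0, 1]")
    if isinstance(dist, Uniform) and not (0.0 <= dist.lo <= dist.hi <= 1.0):
        raise ParameterError(f"{ref.describe()}: uniform({dist.lo}, {dist.hi}) not within [0, 1]")
    if isinstance(dist, Beta) and (dist.alpha <= 0 or dist.beta <= 0):
        raise ParameterError(f"{ref.describe()}: beta parameters must be positive")


@dataclass
class MonteCarloResult:
    """Win proportions and EU summaries over the Monte-Carlo draws.

    ``win_proportions`` sum to 1; ties within a draw split the win
    equally among the tied options so no order bias is introduced.
    """

    win_proportions: Dict[str, float]
    eu_summary: Dict[str, Dict[str, float]]
    n: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "win_proportions": dict(self.win_proportions),
            "eu_summary": {k: dict(v) for k, v in self.eu_summary.items()},
        }


def monte_carlo(
    tree: DecisionTree,
    spec: UncertaintySpec,
    n: int = DEFAULT_MC_DRAWS,
    seed: int = None,  # type: ignore[assignment]
    max_rejects: int = 1000,
) -> MonteCarloResult:
    """Multivariate Monte-Carlo sensitivity analysis.

    For each of ``n`` independent draws every uncertain parameter is
    sampled, affected chance nodes are kept summing to 1 (two-branch
    complement, proportional rescale, or joint Dirichlet), the tree is
    folded back, and the winning option recorded (ties split equally).
    ``seed`` is required: there is no hidden global RNG, and identical
    ``(tree, spec, n, seed)`` always reproduce the same result.
    """
    if seed is None:
        raise ParameterError("monte_carlo requires an explicit seed")
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    spec.validate_against(tree)
    rng = np.random.default_rng(seed)

    base = tree.copy()  # original proportions for multi-branch rescaling
    work = tree.copy()
    work_nodes = {ref.path: resolve_path(work, ref.path) for ref, _ in spec.probabilities}
    work_nodes.update({path: resolve_path(work, path) for path, _ in spec.dirichlet_nodes})
    work_terms = {ref.path: resolve_path(work, ref.path) for ref, _ in spec.values}
    ord_terms = {
        p: resolve_path(work, p) for pair in spec.orderings for p in pair
    }
    base_nodes = {ref.path: resolve_path(base, ref.path) for ref, _ in spec.probabilities}

    options = [o.label for o in tree.root.options]
    wins = {o: 0.0 for o in options}
    eu_draws = {o: np.empty(n) for o in options}

    for i in range(n):
        for _ in range(max_rejects):
            # terminal values first (orderings are checked on them)
            for ref, dist in spec.values:
                work_terms[ref.path].value = _sample(dist, rng)
            ok = all(
                ord_terms[low].value <= ord_terms[high].value
                for low, high in spec.orderings
            )
            if ok:
                break
        else:
            raise DomainError(
                f"ordering constraints rejected {max_rejects} consecutive draws"
            )
        for ref, dist in spec.probabilities:
            node = work_nodes[ref.path]
            p = _sample(dist, rng)
            others_base = [b.p for b in base_nodes[ref.path].branches if b.label != ref.branch]
            rest = sum(others_base)
            for b, b0 in zip(node.branches, base_nodes[ref.path].branches):
                if b.label == ref.branch:
                    b.p = p
                elif rest > 0:
                    b.p = b0.p * (1.0 - p) / rest
                else:
                    b.p = (1.0 - p) / len(others_base)
        for path, alphas in spec.dirichlet_nodes:
            draw = rng.dirichlet(alphas)
            for b, p in zip(work_nodes[path].branches, draw):
                b.p = float(p)

        res = fold_back(work)
        best = max(res.option_values.values())
        tied = [o for o in options if res.option_values[o] == best]
        for o in tied:
            wins[o] += 1.0 / len(tied)
        for o in options:
            eu_draws[o][i] = res.option_values[o]

    summary = {
        o: {
            "mean": float(np.mean(eu_draws[o])),
            "q2.5": float(np.percentile(eu_draws[o], 2.5)),
            "q97.5": float(np.percentile(eu_draws[o], 97.5)),
        }
        for o in options
    }
    return MonteCarloResult(
        win_proportions={o: wins[o] / n for o in options},
        eu_summary=summary,
        n=n,
        seed=seed,
    )
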