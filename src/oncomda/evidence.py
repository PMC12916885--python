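"""Translating clinical evidence and patient preferences into tree parameters.

This module holds the scalar bridges between published evidence (survival
curves, waterfall plots, diagnostic test characteristics) or elicited
preferences (standard gamble) and the probabilities and values that
populate a decision tree:

* standard-gamble utility elicitation and QALY arithmetic;
* relative vs absolute risk reduction, including reading a relative risk
  reduction off the plateaus of relapse-free survival curves;
* event probabilities in a follow-up window from a survival step curve;
* discretization of a progression-free-survival curve into benefit bins;
* true/false positive/negative probabilities from relapse risk plus test
  sensitivity and specificity;
* the probability of reaching a clinically set regression threshold from
  a waterfall plot.

Survival curves are right-continuous step functions, the Kaplan-Meier
convention: S(t) is the value at the latest tabulated time <= t, and
S(0) = 1 is implied.  No silent extrapolation beyond the tabulated
support is ever performed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tree_model import DomainError, ExtrapolationError, check_probability

__all__ = [
    "SurvivalCurve",
    "WaterfallData",
    "TestCharacteristics",
    "QalySegment",
    "PfsBin",
    "standard_gamble_utility",
    "elicitation_round",
    "qaly",
    "absolute_risk_reduction",
    "adjuvant_cure_probability",
    "rrr_from_plateaus",
    "event_probability_in_window",
    "test_outcome_probabilities",
    "waterfall_probability",
    "discretize_pfs",
]

#: Elicitation granularity: subjective probabilities are realistically
#: guessed by steps of 0.05, except for very low probabilities.
ELICITATION_STEP = 0.05


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """A tabulated survival (or relapse-free / progression-free) curve.

    ``times`` must be strictly increasing and non-negative; ``survival``
    non-increasing with values in [0, 1].  The curve is read as a
    right-continuous step function with S(0) = 1 implied, so a leading
    (0, 1) point is optional.
    """

    times: np.ndarray
    survival: np.ndarray
    time_unit: str = "months"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.survival.shape:
            raise DomainError("times and survival must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise DomainError("survival curve must have at least one point")
        if np.any(self.times < 0):
            raise DomainError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise DomainError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 0):
            raise DomainError("survival must be non-increasing")
        if self.times[0] > 0 and self.survival[0] > 1:
            raise DomainError("survival cannot exceed 1")

    @property
    def support_end(self) -> float:
        return float(self.times[-1])

    def S(self, t: float) -> float:
        """Right-continuous step lookup of S(t) within the tabulated support."""
        if t < 0 or t > self.support_end:
            raise ExtrapolationError(
                f"t={t} outside curve support [0, {self.support_end}] "
                f"({self.time_unit}); no silent extrapolation"
            )
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            return 1.0  # S(0)=1 before the first tabulated time
        return float(self.survival[idx])

    # -- plain-text CSV interchange -------------------------------------
    @classmethod
    def from_csv(cls, text_or_path: str) -> "SurvivalCurve":
        """Read a ``time,survival`` CSV; a ``# time_unit: <unit>`` comment
        line declares the unit (default months)."""
        text = _read_text(text_or_path)
        unit = "months"
        for line in text.splitlines():
            if line.startswith("#") and "time_unit" in line:
                unit = line.split(":", 1)[1].strip()
        df = pd.read_csv(io.StringIO(text), comment="#")
        if not {"time", "survival"} <= set(df.columns):
            raise DomainError("curve CSV needs 'time' and 'survival' columns")
        return cls(df["time"].to_numpy(), df["survival"].to_numpy(), time_unit=unit)

    def to_csv(self) -> str:
        lines = [f"# time_unit: {self.time_unit}", "time,survival"]
        lines += [f"{t:g},{s:g}" for t, s in zip(self.times, self.survival)]
        return "\n".join(lines) + "\n"


@dataclass
class WaterfallData:
    """Per-patient best percent change in tumor size; negative = regression."""

    pct_change: List[float]

    def __post_init__(self) -> None:
        if not self.pct_change:
            raise DomainError("waterfall data must be non-empty")
        if any(v < -100 for v in self.pct_change):
            raise DomainError("percent change cannot be below -100 (complete disappearance)")
        self.pct_change = [float(v) for v in self.pct_change]

    @classmethod
    def from_csv(cls, text_or_path: str) -> "WaterfallData":
        df = pd.read_csv(io.StringIO(_read_text(text_or_path)), comment="#")
        if "pct_change" not in df.columns:
            raise DomainError("waterfall CSV needs a 'pct_change' column")
        return cls(df["pct_change"].to_list())

    def to_csv(self) -> str:
        lines = ["patient_id,pct_change"]
        lines += [f"{i + 1},{v:g}" for i, v in enumerate(self.pct_change)]
        return "\n".join(lines) + "\n"


def _read_text(text_or_path: str) -> str:
    if "\n" in text_or_path or "," in text_or_path:
        return text_or_path
    with open(text_or_path) as fh:
        return fh.read()


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity and specificity of a diagnostic exam."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        check_probability(self.sensitivity, "sensitivity")
        check_probability(self.specificity, "specificity")


@dataclass(frozen=True)
class QalySegment:
    """A stretch of life of given duration (years) lived at a given utility."""

    duration: float
    utility: float

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise DomainError(f"segment duration must be >= 0, got {self.duration}")
        check_probability(self.utility, "utility")


@dataclass(frozen=True)
class PfsBin:
    """One discretized progression-free-survival interval."""

    label: str
    probability: float
    duration: float  # representative duration, curve time units


# ---------------------------------------------------------------------------
# Preference elicitation and QALYs
# ---------------------------------------------------------------------------

def elicitation_round(p: float, step: float = ELICITATION_STEP) -> float:
    """Round a probability/utility to the nearest elicitation step.

    Values that would round to an extreme they have not actually reached
    are returned unchanged: a small but non-zero probability is never
    rounded to 0, nor a sub-certain one to 1.
    """
    check_probability(p, "value")
    r = round(p / step) * step
    if (r == 0.0 and p > 0.0) or (r >= 1.0 and p < 1.0):
        return p
    return round(r, 10)


def standard_gamble_utility(p_worst_accepted: float, granular: bool = False) -> float:
    """Utility of an intermediate outcome from the standard gamble.

    A patient indifferent between the certainty of the intermediate
    outcome and a gamble with probability ``p`` of the worst outcome (and
    ``1 - p`` of the best) values the intermediate outcome at ``1 - p``.
    With ``granular=True`` the result is rounded to the nearest 0.05
    elicitation step (never silently to an extreme).
    """
    p = check_probability(p_worst_accepted, "accepted worst-outcome probability")
    u = 1.0 - p
    return elicitation_round(u) if granular else u


def qaly(segments: Sequence[QalySegment | Tuple[float, float]]) -> float:
    """Quality-adjusted life years: sum of duration_i x utility_i.

    Segments may be :class:`QalySegment` or plain ``(duration, utility)``
    tuples.  E.g. 10 years at utility 0.9 -> 9 QALYs.
    """
    if not segments:
        raise DomainError("qaly needs at least one segment")
    total = 0.0
    for seg in segments:
        if not isinstance(seg, QalySegment):
            seg = QalySegment(*seg)
        total += seg.duration * seg.utility
    return total


# ---------------------------------------------------------------------------
# Risk reductions
# ---------------------------------------------------------------------------

def absolute_risk_reduction(baseline_risk: float, rrr: float) -> float:
    """Absolute risk reduction = baseline risk x relative risk reduction.

    The same relative reduction means very different absolute gains across
    baselines: 20% relative on a 50% baseline is 10 points, on a 5%
    baseline only 1.
    """
    b = check_probability(baseline_risk, "baseline risk")
    r = check_probability(rrr, "relative risk reduction")
    return b * r


def adjuvant_cure_probability(p_cure_baseline: float, rrr: float) -> float:
    """Cure probability after adding a therapy that cuts relapse risk by ``rrr``.

    The relapse risk ``1 - p_cure`` shrinks by the relative risk
    reduction: result = p + (1 - p) * rrr.
    """
    p = check_probability(p_cure_baseline, "baseline cure probability")
    r = check_probability(rrr, "relative risk reduction")
    return p + (1.0 - p) * r


def rrr_from_plateaus(plateau_control: float, plateau_treated: float) -> float:
    """Relative risk reduction read off the plateaus of two survival curves.

    With long-term event-free fractions ``s0`` (control) and ``s1``
    (treated), the relative risk reduction is
    ``((1 - s0) - (1 - s1)) / (1 - s0)``.  A treated plateau below the
    control one yields a negative value (harmful treatment) with a
    warning.
    """
    s0 = check_probability(plateau_control, "control plateau")
    s1 = check_probability(plateau_treated, "treated plateau")
    if s0 == 1.0:
        raise DomainError("control plateau = 1 leaves no baseline risk to reduce")
    rrr = ((1.0 - s0) - (1.0 - s1)) / (1.0 - s0)
    if s1 < s0:
        import warnings

        warnings.warn(
            "treated plateau below control plateau: negative relative risk "
            "reduction (harmful treatment)",
            stacklevel=2,
        )
    return rrr


# ---------------------------------------------------------------------------
# Survival-curve reads
# ---------------------------------------------------------------------------

def event_probability_in_window(
    curve: SurvivalCurve,
    t_start: float,
    t_end: float,
    conditional: bool = True,
) -> float:
    """Probability of the event inside the window [t_start, t_end].

    Conditional (default) on being event-free at the window start —
    the bedside question at a scheduled follow-up visit:
    ``(S(t_start) - S(t_end)) / S(t_start)``.  Unconditional mode returns
    the cumulative difference ``S(t_start) - S(t_end)``.
    """
    if not (0 <= t_start <= t_end):
        raise DomainError(f"need 0 <= t_start <= t_end, got [{t_start}, {t_end}]")
    s0 = curve.S(t_start)
    s1 = curve.S(t_end)
    if not conditional:
        return s0 - s1
    if s0 <= 0:
        raise DomainError(f"S(t_start)={s0}: cannot condition on an impossible state")
    return (s0 - s1) / s0


def discretize_pfs(
    curve: SurvivalCurve,
    cutpoints: Sequence[float],
    representative: str = "midpoint",
) -> List[PfsBin]:
    """Break a progression-free-survival curve into probability/duration bins.

    With cutpoints ``c_1 < ... < c_k`` the bins are ``[0, c_1)``,
    ``[c_1, c_2)``, ..., ``[c_k, end]`` with probabilities
    ``S(c_{j-1}) - S(c_j)`` and, for the last bin, ``S(c_k)``; they
    telescope to 1.  Each bin carries a representative duration — the
    interval midpoint by default (the last, open-ended bin uses ``c_k``);
    ``representative="start"`` uses the interval start instead.
    """
    cps = [float(c) for c in cutpoints]
    if not cps:
        raise DomainError("need at least one cutpoint")
    if any(b <= a for a, b in zip(cps, cps[1:])):
        raise DomainError("cutpoints must be strictly increasing")
    if cps[0] <= 0:
        raise DomainError("cutpoints must be positive")
    if cps[-1] > curve.support_end:
        raise ExtrapolationError(
            f"cutpoint {cps[-1]} outside curve support [0, {curve.support_end}]"
        )
    if representative not in ("midpoint", "start"):
        raise DomainError("representative must be 'midpoint' or 'start'")

    bins: List[PfsBin] = []
    prev_t, prev_s = 0.0, 1.0
    for c in cps:
        s = curve.S(c)
        rep = (prev_t + c) / 2.0 if representative == "midpoint" else prev_t
        bins.append(
            PfsBin(
                label=f"progression in [{prev_t:g}, {c:g}) {curve.time_unit}",
                probability=prev_s - s,
                duration=rep,
            )
        )
        prev_t, prev_s = c, s
    bins.append(
        PfsBin(
            label=f"progression-free >= {prev_t:g} {curve.time_unit}",
            probability=prev_s,
            duration=prev_t,
        )
    )
    return bins


# ---------------------------------------------------------------------------
# Diagnostic tests and waterfall plots
# ---------------------------------------------------------------------------

def test_outcome_probabilities(
    p_event: float, test: TestCharacteristics
) -> Dict[str, float]:
    """Joint probabilities of the four test-x-relapse outcomes.

    TP = p*sens, FN = p*(1-sens), FP = (1-p)*(1-spec), TN = (1-p)*spec;
    the four always sum to 1.
    """
    p = check_probability(p_event, "event probability")
    return {
        "TP": p * test.sensitivity,
        "FN": p * (1.0 - test.sensitivity),
        "FP": (1.0 - p) * (1.0 - test.specificity),
        "TN": (1.0 - p) * test.specificity,
    }


def waterfall_probability(data: WaterfallData, regression_threshold_pct: float) -> float:
    """Fraction of patients reaching at least the given percent regression.

    A patient counts if their best percent change is <= minus the
    threshold; reaching exactly the threshold counts (achieving a 50%
    regression includes exactly 50%).  The threshold is the clinically
    required regression for the case at hand, not a research convention.
    """
    if regression_threshold_pct < 0:
        raise DomainError("regression threshold must be a non-negative percent")
    n = len(data.pct_change)
    hits = sum(1 for v in data.pct_change if v <= -regression_threshold_pct)
    return hits / n
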