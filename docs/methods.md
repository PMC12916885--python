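# Methods

## The model

A decision problem is a finite rooted tree.  The root is a decision
node; below it, decision nodes, chance nodes, and terminal nodes may
interleave arbitrarily (embedded decisions are allowed at any depth —
the model imposes no bound, since none is inherent to the method).
Chance-node branch probabilities must be exhaustive and mutually
exclusive, hence sum to 1; this is enforced with an absolute tolerance
of 1e-9, chosen so that elicited values (realistically guessed on a
0.05 grid) and float round-off can never fail validation while any
genuine modelling error (the smallest meaningful discrepancy being
~0.01) always does.  A two-branch chance node may specify only one
probability; the complement is filled automatically.

Outcome values live on a single tree-level *measure* — `utility`
(unitless, in [0, 1]), `life_years`, or `qaly` — rather than
per-terminal, so every expected value is dimensionally coherent.
Terminal values may be absent altogether, leaving a purely
probabilistic tree usable for risk analysis only.

Nodes are addressed by the slash-joined branch labels from the root
(`"surgery alone/cure"`); the root has the empty path.  This addressing
is stable under re-serialization and is what validation reports,
policies, and sensitivity parameters use.

## Evaluation

Fold-back computes chance-node values as probability-weighted sums of
child values and decision-node values as maxima over options.
Expected values are exact floating-point sums in tree order; no
compensated summation is used because bedside trees have at most a few
dozen terminals.  Ties at a decision node are broken in favour of the
first-listed option — deterministic and author-controlled — and every
tie is reported.  Since templates list the intervention under
consideration first, a tie there resolves toward the intervention;
re-order the options to change that.

Risk analysis sums path probabilities into outcome labels per root
option.  On trees with embedded decision nodes the profile is only
defined relative to a policy; by default the EU-optimal choices from
fold-back are used (including at decision nodes unreachable under the
optimal root choice, so that *every* root option gets a profile), and
any explicit policy can be supplied instead.  The engine does not rank
non-optimal policies beyond their expected utility.  Outcomes that
share a value but differ clinically (early toxic death vs death after
relapse, both utility 0) keep distinct labels so risk analysis keeps
them apart.

## Evidence translators

* Standard gamble: `u = 1 − p_worst_accepted`.  An opt-in granular
  mode rounds to the nearest 0.05, reflecting realistic elicitation
  coarseness; rounding is never silent and never collapses a non-zero
  probability to 0 (or a sub-certain one to 1), because very low
  probabilities are exactly where the 0.05 grid is too coarse.
* QALYs: Σ duration × utility over life segments.
* Risk reductions: `ARR = baseline × RRR`;
  `p_cure_adjuvant = p + (1 − p)·RRR`.  The two parameterizations are
  algebraically the same statement about the complementary risk.  When
  an RRR read off one trial population is re-applied to a different
  baseline risk, the transferability of the relative effect is an
  *assumption* the engine surfaces in documentation but cannot check.
* Survival curves are right-continuous step functions (the
  Kaplan-Meier convention): S(t) is the value at the latest tabulated
  time ≤ t, S(0) = 1 implied.  Queries beyond the tabulated support
  raise an extrapolation error; the engine never extrapolates
  silently.  Curve plateaus are supplied by the user as scalars, not
  auto-detected: locating a plateau on a published curve is a clinical
  judgement.
* Follow-up window risk defaults to *conditional* on being event-free
  at the window start — the question actually asked at a scheduled
  visit — with the unconditional cumulative difference available.
* PFS discretization: bin probabilities are successive survival
  differences, telescoping to 1.  Each bin needs a single
  representative duration; the interval midpoint is the default (the
  open-ended last bin uses its left edge), with `representative="start"`
  as the conservative alternative.  No rule is canonical here; the
  choice is documented and overridable.
* Waterfall reads count patients at or beyond the clinically required
  regression (ties included: "achieving a 50% regression" includes
  exactly 50%).

## Sensitivity analysis

Setting a chance probability keeps its node coherent: the two-branch
complement moves oppositely; on wider nodes the remaining branches are
rescaled proportionally to their original shares.  Expected utility of
any option is affine in any single chance probability, so one-way
plots are straight lines and every crossing is simple.  The default
one-way grid is 101 equally spaced points on [0, 1].

Threshold finding scans the admissible interval coarsely, then bisects
each sign-change bracket of the EU difference until
|EU_a − EU_b| ≤ 1e-10 (at most 200 iterations).  The stopping rule is
on the utility gap, not the parameter: where the gap is flat in the
parameter, the parameter location is correspondingly loose, which is
the right behaviour for a break-even question.  Absence of a sign
change is reported as a no-threshold result, not an error — dominance
is an answer.

Monte-Carlo analysis samples every uncertain parameter independently
per draw (the method states no correlation structure between
probabilities and utilities; independence is the documented
assumption), refolds the tree, and counts wins.  Chance nodes with
more than two uncertain branches must be sampled jointly from a
Dirichlet so the node sums to 1 without biasing any branch;
independently-sampled-then-renormalized branches would not be
exchangeable.  Ties in a draw split the win equally among tied
options, keeping proportions summing to 1 without order bias.  The
seed is a required argument — no hidden global RNG — and identical
inputs reproduce identical results.  Default draws: 10,000, which
bounds the Monte-Carlo standard error of a win proportion by 0.5%.
Optional user-declared orderings between terminal utilities (e.g.
cure-with-sequelae ≤ cure) are enforced by rejection sampling; none is
assumed.

## Templates

Each builder returns a validated tree; option order is fixed with the
intervention first.  Template-specific choices:

* **Expanded trade-off**: systemic cure after conservative treatment
  is modelled on the no-local-relapse branch; the relapse branch goes
  through rescue (organ removal) and then a post-rescue cure chance
  whose probability is a free parameter with *no default*, because the
  systemic risk after a rescued relapse may range from nil through the
  original baseline to worse.  At zero local-relapse probability the
  arm reduces exactly to the basic template.
* **Adjuvant**: the optional fatal-toxicity node precedes the cure
  chance; its terminal is labelled "early toxic death", distinct from
  "relapse" despite equal utility.  An optional utility for time on
  therapy discounts the adjuvant arm's cure terminal.  At zero
  toxicity probability the EU reduces exactly to the plain template.
* **Cytoreduction**: the mutilating-now arm carries no local-relapse
  node (a stated simplification; graft one on if the case demands it).
  The insufficient-regression branch splits into resectability lost
  (terminal, `u_unresectable`) vs salvage mutilating surgery with its
  own cure probability.
* **Surveillance**: life under surveillance without evolution carries
  utility `u_no_treatment_morbidity` (default 1); delayed treatment
  shares the immediate arm's sequelae utility — whether delayed
  sequelae should differ is genuinely open, so the parameter structure
  keeps them equal by construction and a custom tree covers the rest.
* **Advanced disease**: options are described by clinical-benefit bins
  (probability + representative duration), typically from a
  discretized PFS curve, precisely to avoid collapsing responders and
  non-responders into one median.  What counts as "benefit" (response
  depth, minimum duration) is agreed between clinician and patient
  upstream; the template takes the resulting probabilities as inputs
  rather than re-deriving them.  Best supportive care is always an
  option — "no treatment" is a treatment.
* **Follow-up subtree**: a four-branch chance node (TP/FN/FP/TN) with
  placeholder terminals for the caller to replace when embedding.

## Synthetic fixtures

The fixture generator emulates the *structure* of bedside trees, not
any disease: random depth-bounded trees whose chance probabilities are
drawn on the 0.05 elicitation lattice and renormalized, with embedded
decision nodes appearing at a modest rate (default 0.15 per internal
node) as they do in practice.  Survival fixtures are random
non-increasing step curves with an optional plateau tail, emulating
published relapse-free/PFS curves.  Both are deterministic given their
seed.  What passing tests on these fixtures shows is that the
*arithmetic* — fold-back, conservation, risk profiles, sensitivity —
is correct on arbitrary valid inputs; they say nothing about whether
any particular clinical parameterization is realistic, which is
irreducibly the clinician's judgement.

Test problem sizes: structural properties run on hundreds of generated
trees (depths 3-6); the fold-back-vs-enumeration cross-check runs on
200 trees of depth ≤ 5 restricted to at most six embedded decision
nodes so the exhaustive policy enumeration it is checked against stays
exact; Monte-Carlo calibration checks use 10,000 draws, matching the
default.  The whole suite completes in a few seconds.

## Known limitations

* No Markov state-transition modelling: transitions over time across
  health states belong to cohort/economic analysis, which is out of
  scope for a single-patient bedside tool.
* No Bayesian machinery for turning trial reports into probability
  distributions; distributions are user-supplied.
* No Kaplan-Meier estimation from raw time-to-event data, confidence
  intervals on curve reads, automated plateau detection, or RECIST
  classification: curves and thresholds enter as the clinician reads
  them.
* No expected value of perfect information, variance-based sensitivity
  indices, or correlated sampling.
* Risk profiles condition on a single policy; the engine does not
  enumerate or rank policies beyond expected utility.
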