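# oncomda — bedside medical decision analysis for oncology

Medical decision analysis structures a clinical decision as a tree of
**decision nodes** (the physician chooses among mutually exclusive
options), **chance nodes** (nature resolves among mutually exclusive
events, with probabilities summing to 1), and **terminal nodes** (final
outcomes carrying a value).  Folding the tree back from its leaves —
expectations at chance nodes, maxima at decision nodes — yields the
expected utility of each option:

```
EU(option) = Σ_paths  (Π_i p_i) · v(terminal)
```

with the decision rule *maximize expected utility*.  Terminal values can
be patient utilities on [0, 1] (elicited by the **standard gamble**: a
patient who accepts at most probability *p* of the worst outcome to
avoid an intermediate one values that outcome at *1 − p*), life-years,
or quality-adjusted life-years (QALYs, duration × utility).  Kept purely
probabilistic, the same tree yields a **risk analysis** — the
probability of each final outcome under each option — which is often
more useful to the patient than any utility maximization.

`oncomda` is a small engine for doing this at the individual-patient
level rather than in health-economic cohort models.  It provides:

* a JSON-serializable decision-tree model with validation
  (probability conservation at every chance node, utility ranges,
  structural soundness) and Graphviz DOT export;
* exact fold-back, optimal-policy extraction, path enumeration, and
  per-option risk profiles;
* evidence translators: standard-gamble utilities, QALYs, relative →
  absolute risk reduction (`ARR = baseline risk × RRR`), risk
  reductions read off survival-curve plateaus, event probabilities in a
  follow-up window of a Kaplan-Meier-style step curve, discretization
  of progression-free-survival curves into benefit bins, diagnostic
  true/false positive/negative probabilities from sensitivity and
  specificity, and response probabilities read off waterfall plots;
* sensitivity analysis: one-way and two-way parameter sweeps, threshold
  (break-even) finding by bisection, and multivariate Monte-Carlo
  analysis over per-parameter distributions (point, uniform, beta, and
  joint Dirichlet for whole chance nodes) reporting each option's win
  proportion;
* parameterized templates for six recurring oncology decisions:
  quantity/quality-of-life trade-off (basic and with local-relapse
  rescue), adjuvant therapy (optionally with fatal toxicity),
  cytoreduction for conversion to conservative surgery, active
  surveillance vs immediate treatment, advanced-disease treatment vs
  best supportive care, and a follow-up testing chance node.

It is written for clinicians-methodologists and biostatisticians who
want scriptable, reproducible decision models, and as a teaching tool.

## Worked example: adjuvant therapy

A patient has a 50% probability of cure with surgery alone; an adjuvant
therapy offers a 20% relative reduction of the relapse risk.  Build and
evaluate the tree from the shell:

```bash
oncomda template adjuvant --p-cure-surgery-alone 0.5 --rrr 0.2 --evaluate
```

```
option                         expected utility
-----------------------------  ----------------  -------
surgery plus adjuvant therapy  0.6000            <- best
surgery alone                  0.5000

option                         outcome  probability
-----------------------------  -------  -----------
surgery plus adjuvant therapy  cure     0.600
surgery plus adjuvant therapy  relapse  0.400
surgery alone                  cure     0.500
surgery alone                  relapse  0.500
```

With 1/0 utilities the expected utility is an expected probability of
cure, so the risk analysis exposes the **absolute** risk reduction this
patient can expect: 0.600 − 0.500 = 10 percentage points.  The same 20%
relative reduction on a 5% baseline risk (`--p-cure-surgery-alone
0.95`) yields only 1 point — the distinction that matters when
informing a patient.  The same trees are available in Python
(`oncomda.adjuvant_tree`, `oncomda.fold_back`,
`oncomda.risk_analysis`), and every other subcommand (`oneway`,
`twoway`, `threshold`, `montecarlo`, `export-dot`, `fixture`,
`validate`) reads and writes the same tree JSON.

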