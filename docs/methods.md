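# Methods

## The model

`boolsynergy` works with Boolean models of signaling networks.  A model
is a signed directed graph (activation +1, inhibition −1) together with
one logical rule per core node, always of the template

    X = (A₁ OR … OR Aₘ) ⟨op⟩ NOT (I₁ OR … OR Iₖ)

where the Aᵢ are X's activators, the Iⱼ its inhibitors and ⟨op⟩ — the
*link operator* — is either `AND` (an active inhibitor always silences
the node) or `OR` (either an active activator or a silent inhibitor
clause suffices).  Nodes with only one kind of regulator reduce to
`OR(activators)` or `NOT OR(inhibitors)`; regulator-free nodes are free
inputs.  A source that both activates and inhibits the same target
(dual regulation) simply appears in both clauses; no special case is
made, because the signed edge list preserves both interactions.

The dynamics of interest are **fixed points** (stable states): total
0/1 assignments mapped to themselves by every rule.  Cyclic attractors
are deliberately out of scope; a model with no fixed point is a legal,
reportable outcome (its response is NA).  The solver runs iterated
constant propagation — any rule whose value is already forced by the
partial assignment pins its node — followed by backtracking over the
remaining free variables, with propagation re-applied after each
branch.  It is exact: the test suite checks equality with exhaustive
2ⁿ enumeration on hundreds of random models, with and without clamps.
Free inputs are genuine free variables (both values explored); callers
who want a fixed environment clamp them.  Returned states are sorted
lexicographically in node order, so results are byte-stable.  A
configurable node cap (default 512) guards against accidental
exponential blow-ups.

Two **multivalued phenotype outputs**, `Prosurvival` and
`Antisurvival`, summarize a fixed point.  Each has signed regulator
nodes; its level is the net count of active regulators (positives minus
negatives) saturated into 0–3.  This is the simplest monotone rule
reproducing the documented 0–3 local range; it is a package decision
where only "regulators add additively" is fixed, and the regulator
signs make it configurable per phenotype definition.  The **global
state** is Prosurvival − Antisurvival ∈ [−3, +3]: −3 purely
anti-survival (cell death), +3 purely pro-survival.  A model's
**response** under a perturbation is the mean global state over its
fixed points (NA when there are none, with the fixed-point count
reported so downstream steps can demand a quorum).

## Perturbations and synergy

Drugs are hard clamps: an inhibitor forces its target nodes to 0, an
activator to 1, for the whole simulation — matching screens where drugs
are characterized by target profiling rather than dose–response.  A
condition is untreated, one drug, or an unordered pair; conflicting
clamps on one node are rejected at construction.  For n drugs the grid
is 1 + n + n(n−1)/2 conditions (18 drugs → 153 pairs, 19 → 171).

Synergy uses the strict min rule, per model: a pair is synergistic when
its response is *strictly below* the minimum of the two single-drug
responses (an HSA-style criterion on the global state; ties are
non-synergistic).  Over an ensemble, `vote_fraction` is the fraction of
models (with all three responses defined) voting synergy; the binary
call thresholds it (default 0.5).  `excess` — the mean of
min(single) − pair — is kept as the continuous ranking score for ROC
evaluation, since a vote fraction ties heavily.

## Calibration (genetic algorithm)

Training data are binary steady-state activities for a subset of nodes.
Fitness of a model is, per fixed point, the weighted fraction of
observed nodes matching; aggregated over fixed points by mean (default)
or max.  The max aggregation is the right choice when the profile is
known to describe a single biological attractor — a model may hold the
matching state among several alternatives without penalty; the mean is
the unbiased default when no attractor is singled out.  Note the mean
caps below 1 for any multi-attractor model, so recovery experiments
against single-attractor profiles use `fitness_aggregate="max"`.

The GA mutates only link operators (topology is never touched): a child
is a copy of an elite parent with the operator toggled at
`mutations_per_child` uniformly drawn mutable loci (with replacement).
Selection is elitist — the top `elite` models survive unchanged, ties
broken by model id, so best fitness is non-decreasing within a run —
and there is no crossover (mutation–selection only; the config object
is the extension point).  Each of `runs` independent restarts
contributes its final best model to the ensemble if it reaches
`fitness_threshold`.  Defaults: population 20, generations 20, elite 3,
3 mutations/child, 50 runs, threshold 0 — engineering choices surfaced
in `GAConfig`.  Everything is reproducible from `seed` via per-run
spawned generator streams.

A profile-intersection utility (`restrict_to_common`) supports
training-set reduction: restricting a broad profile to the nodes a
smaller profile also predicts, for like-for-like comparisons between
training sets.

## Evaluation statistics

Implemented from definitions, so each is testable against an
enumeration oracle; scipy backs only distribution CDFs.

* **ROC/AUC** — Mann–Whitney with half credit for pos/neg ties (needed
  for heavily tied vote fractions); the curve groups tied scores into
  one step.
* **Wilcoxon signed rank** (paired) — zero differences dropped,
  midranks for ties; for ≤ 25 non-zero differences the p-value is exact
  over the null distribution of all sign patterns (computed by
  subset-sum dynamic programming over doubled midranks — identical to
  literal 2ⁿ enumeration); larger samples use the normal approximation
  with tie and continuity correction.
* **One-sided t-tests** — paired, and Welch for two samples (the
  unpaired/paired choice is exposed because either may be appropriate
  when comparing performance across training sets); zero-variance
  degenerate input returns p = 0.5 flagged.
* **Benjamini–Hochberg** step-up adjustment, reported in input order.

## Gap analysis

The "middle-out" step asks where condition-specific biology outruns a
curated model.  Inputs are already-thresholded affected-gene lists (one
per condition — upstream differential-expression / copy-number /
mutation tools are consumed, not re-implemented), a GMT gene-set
collection, and optionally the model's node→gene-symbol annotation.
Per condition, overrepresentation is the upper-tail hypergeometric test
with BH correction across sets (significant at adjusted p < 0.05).
Venn-region counts over 2–4 lists support overlap reporting.  The
coverage matrix is binary: rows are sets significant somewhere or
covered by the model, columns the conditions plus a `model` column; a
**gap** is a row significant in some condition with model coverage 0.
Model coverage of a set is decided by a minimum-overlap rule (default
≥ 2 model genes in the set) computed from the annotation file — which
is therefore required for this feature and errors loudly when absent.

## Synthetic ground truth

`generate_network` builds a 30-node (default) weakly connected signed
digraph: 2 free inputs; each other node draws 1 + Poisson(mean−1)
regulators with sources biased toward nodes that already regulate many
targets (hub mimicry via preferential attachment on out-degree); edge
signs are inhibitory with probability 0.3, and a node that drew only
inhibitors receives one extra activating edge (added, not flipped, so
the realized sign mix stays calibrated).  The last 6 + 6 nodes are
wired as positive regulators of Prosurvival and Antisurvival, so both
phenotype levels can reach 0–3.  The default mean in-degree of 3.0 was
chosen because min-rule synergy requires convergent, OR-redundant
regulation; sparser wiring yields screens with essentially no
synergistic pairs, which would make end-to-end evaluation vacuous.

`make_instance` samples link operators uniformly (resampling, bounded
retries, until a fixed point exists), picks one fixed point as the
biological state, observes a fraction of nodes (default 0.8) with
per-observation flip probability (default 0, i.e., noiseless), draws
8 inhibitors of 1–2 non-phenotype-regulator nodes each, and derives
truth synergy labels by running the truth model itself through the
perturbation and min-rule machinery.  Observed agreement with the
truth state is 1 − flip_prob in expectation.

What passing tests show — and what they do not: the generator matches
the *shapes* the pipeline assumes (signed hub-heavy topology, binary
single-attractor observations with dropout and flips, target-profiled
inhibitors, rare synergies), so recovery results demonstrate that the
machinery can invert its own generative process.  Real training data
add inference error, correlated noise, unmodeled nodes and graded drug
effects; nothing here quantifies performance under those.

## Problem sizes and numerical choices

The recovery experiment in the acceptance suite uses 30-node instances,
10 seeds, GA at population 20 / 20 generations / elite 3 / 8 runs with
max aggregation — sizes chosen to exercise every stage at desk scale.
Because realistic instances carry few synergistic pairs (often zero per
~28-pair panel, matching the low prevalence of real screens), the
recovery AUC pools scores and truth labels across seeds rather than
averaging per-seed AUCs, which would frequently be undefined.
Solver ties are impossible (states are discrete); ordering ties in the
GA are broken by model id; all randomness flows from explicit seeds
(numpy `SeedSequence` spawning).

## Known limitations

* Only fixed points; models whose behavior lives in cyclic attractors
  report NA responses.
* Hard clamps cannot express partial target inhibition or off-target
  gradients.
* The phenotype integer mapping (net active regulators, saturated) is
  one of several defensible "additive" readings.
* The backtracking solver is exponential in the worst case; the node
  cap and reduction make typical curated-network sizes practical, but
  adversarial dense networks are not.
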