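# boolsynergy

Boolean logical-model ensembles for predicting drug-combination synergy
in signaling networks.

Anti-cancer drug combinations are screened experimentally at great
cost; logical models of the signaling network behind a cell line offer
a cheap *in silico* pre-screen.  `boolsynergy` implements that pipeline
for computational systems biologists: start from a curated signed
network (SIF), build Boolean rules of the fixed template
`X = (A₁ OR … OR Aₘ) AND/OR NOT (I₁ OR … OR Iₖ)`, calibrate the
link operators against binary steady-state training data with a
genetic algorithm, simulate single and pairwise drug inhibitions on
the resulting model ensemble, and call a pair synergistic when its
predicted viability drops strictly below the better of the two single
agents (an HSA-style min rule).

Viability is read off each stable state through two multivalued
phenotype outputs — `Prosurvival` and `Antisurvival`, local states
0–3 — combined into a global output state

    G = Prosurvival − Antisurvival ∈ [−3, +3]

with −3 purely pro-death and +3 purely pro-survival.  A drug pair
(a, b) is synergistic for a model when G(a,b) < min(G(a), G(b)).

The package also ships the supporting machinery: an exact fixed-point
solver (constant propagation + backtracking, verified against
exhaustive enumeration), ROC/AUC / Wilcoxon / t-test / BH-FDR
statistics implemented from their definitions, an enrichment-based
"gap analysis" that flags pathways significant in omics data but
missing from a model, and a synthetic ground-truth generator so every
stage is testable end to end without external data.  See
`docs/methods.md` for the model and its assumptions.

## Worked example

A toy network with two redundant survival pathways (`P1→P2`, `Q1→Q2`)
feeding the same pro-survival effectors — the classic setting where
blocking either pathway alone does little but blocking both collapses
survival:

```python
from boolsynergy import (two_pathway_toy, ModelEnsemble,
                         ensemble_responses, score_panel)

network, model, panel = two_pathway_toy()   # inhibitors of P1, P2, Q1
ensemble = ModelEnsemble(models=[model], fitnesses=[1.0])
table = ensemble_responses(ensemble, panel)
for cid in ("untreated", "antiP1", "antiQ1", "antiP1+antiQ1"):
    print(cid, table[cid].mean_response)
for c in score_panel(table, panel):
    print(f"{c.drug_a}+{c.drug_b}: excess={c.excess:+.1f} "
          f"vote={c.vote_fraction:.0%} call={c.call}")
```

prints

```
untreated 2.0
antiP1 1.0
antiQ1 1.0
antiP1+antiQ1 -1.0
antiP1+antiP2: excess=+0.0 vote=0% call=False
antiP1+antiQ1: excess=+2.0 vote=100% call=True
antiP2+antiQ1: excess=+2.0 vote=100% call=True
```

Untreated, the free pathway inputs average to a pro-survival state of
+2.0.  Inhibiting one pathway nudges it to +1.0 — the other pathway
sustains the effectors — but inhibiting both drops the global state to
−1.0, strictly below the better single agent, so both cross-pathway
pairs are called synergistic (excess +2.0, unanimous model vote) while
the within-pathway pair, whose combination adds nothing over its
singles, is not.

The full pipeline on synthetic ground truth looks the same with
`generate_network` / `make_instance` supplying the network, training
profile and drug panel, `evolve` fitting the ensemble, and
`roc_auc` scoring predictions against the instance's hidden-truth
synergy labels.

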