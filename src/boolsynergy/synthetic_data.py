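"""Ground-truth instance generation for end-to-end testing.

Real applications of this pipeline start from a curated signed network,
omics-derived binary training profiles and an experimental drug screen.
This module fabricates all three with the statistical structure the
pipeline assumes: a scale-free-ish signed digraph with designated
pro-/anti-survival phenotype regulators, a hidden operator assignment
(the truth model) whose stable state plays the role of the biological
steady state, a noisy partial observation of that state as the training
profile, a panel of node inhibitors, and synergy labels obtained by
running the exact same min rule on the truth model.

What this emulates and what it does not: the generator reproduces the
*shapes* the method consumes (signed hub-heavy topology, binary
steady-state observations with dropout and flips, target-profiled
inhibitors) but not the biology behind them — no pathway structure, no
correlated measurement error, no dose dependence.  Recovery results on
these instances demonstrate the machinery, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .ga_optimizer import ModelEnsemble, TrainingProfile
from .logic_engine import PhenotypeDef, fixed_points
from .network_io import (
    AND_NOT,
    OR_NOT,
    BooleanModel,
    LogicalNetwork,
    SignedEdge,
    default_model,
)
from .perturbation import Drug, ensemble_responses
from .synergy import score_panel

__all__ = [
    "SyntheticInstance",
    "generate_network",
    "make_instance",
    "two_pathway_toy",
]

DEFAULT_N_PRO = 6
DEFAULT_N_ANTI = 6


@dataclass
class SyntheticInstance:
    """A complete ground-truth problem instance.

    ``truth_labels`` maps frozenset({drug_a, drug_b}) to the synergy
    call the hidden truth model itself makes; pairs whose call is
    undefined (no stable state under some condition) are omitted.
    """

    network: LogicalNetwork
    truth_model: BooleanModel
    biological_state: dict
    training_profile: TrainingProfile
    panel: list[Drug]
    truth_labels: dict
    seed: int
    obs_fraction: float
    flip_prob: float


def generate_network(
    n_nodes: int = 30,
    mean_in_degree: float = 3.0,
    inhibitor_fraction: float = 0.3,
    n_pro: int = DEFAULT_N_PRO,
    n_anti: int = DEFAULT_N_ANTI,
    seed: int = 0,
    n_inputs: int = 2,
) -> LogicalNetwork:
    """Random signed regulatory network with phenotype regulators.

    Nodes after the first ``n_inputs`` receive 1 + Poisson(mean-1)
    in-edges whose sources are drawn preferentially towards nodes that
    already regulate many others (hub mimicry).  Edge signs are
    inhibitory with probability ``inhibitor_fraction``; a node that
    drew only inhibitors gets one extra activating edge so every
    regulated node has at least one activator.  The last ``n_pro`` +
    ``n_anti`` non-input nodes are wired as positive regulators of the
    Prosurvival / Antisurvival outputs.  Weak connectivity is enforced
    by bridging stray components with activating edges.
    """
    if n_nodes < 5:
        raise ValueError("need at least 5 nodes")
    if not (0 < inhibitor_fraction < 1):
        raise ValueError("inhibitor_fraction must lie in (0, 1)")
    if mean_in_degree >= n_nodes:
        raise ValueError("mean_in_degree must be below n_nodes")
    if n_pro + n_anti > n_nodes - n_inputs:
        raise ValueError("too many phenotype regulators for this node count")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:03d}" for i in range(n_nodes)]
    out_weight = {n: 1.0 for n in nodes}
    edges: set[tuple[str, str, int]] = set()

    def add_edge(src: str, tgt: str, sign: int) -> None:
        if (src, tgt, sign) not in edges:
            edges.add((src, tgt, sign))
            out_weight[src] += 1.0

    for idx in range(n_inputs, n_nodes):
        tgt = nodes[idx]
        k = 1 + rng.poisson(max(mean_in_degree - 1.0, 0.0))
        candidates = [n for n in nodes if n != tgt]
        w = np.array([out_weight[n] for n in candidates])
        chosen = rng.choice(len(candidates), size=min(k, len(candidates)),
                            replace=False, p=w / w.sum())
        signs = [(-1 if rng.random() < inhibitor_fraction else 1) for _ in chosen]
        for ci, sign in zip(chosen, signs):
            add_edge(candidates[ci], tgt, sign)
        if all(s == -1 for s in signs):
            # guarantee >= 1 activator without biasing the sign mix:
            # add one extra activating edge rather than flipping one
            remaining = [n for n in candidates
                         if (n, tgt, 1) not in edges]
            if remaining:
                w2 = np.array([out_weight[n] for n in remaining])
                extra = remaining[int(rng.choice(len(remaining), p=w2 / w2.sum()))]
                add_edge(extra, tgt, 1)

    # bridge weak components towards the component containing node 0
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from((s, t) for s, t, _ in edges)
    comps = list(nx.weakly_connected_components(g))
    if len(comps) > 1:
        main = max(comps, key=len)
        for comp in comps:
            if comp is main:
                continue
            src = sorted(main)[int(rng.integers(len(main)))]
            tgt_choices = sorted(n for n in comp if nodes.index(n) >= n_inputs)
            tgt = (tgt_choices or sorted(comp))[0]
            add_edge(src, tgt, 1)

    regs = nodes[n_nodes - n_pro - n_anti:]
    pro = PhenotypeDef("Prosurvival", [(n, 1) for n in regs[:n_pro]])
    anti = PhenotypeDef("Antisurvival", [(n, 1) for n in regs[n_pro:]])
    edge_list = [SignedEdge(s, t, sign) for s, t, sign in sorted(edges)]
    return LogicalNetwork(nodes=nodes, edges=edge_list, phenotype_defs=[pro, anti])


def _sample_truth_model(network: LogicalNetwork, rng: np.random.Generator,
                        max_tries: int) -> tuple[BooleanModel, list[dict]]:
    for attempt in range(max_tries):
        model = default_model(network, model_id=f"truth_try{attempt}")
        for tgt in model.mutable_targets():
            op = AND_NOT if rng.integers(2) == 0 else OR_NOT
            model.equations[tgt] = model.equations[tgt].with_operator(op)
        fps = fixed_points(model)
        if fps:
            return model.copy(model_id="truth"), fps
    raise RuntimeError(
        f"no operator assignment with a stable state found in {max_tries} attempts"
    )


def make_instance(
    network: Optional[LogicalNetwork] = None,
    obs_fraction: float = 0.8,
    flip_prob: float = 0.0,
    n_drugs: int = 8,
    max_targets: int = 2,
    seed: int = 0,
    max_tries: int = 50,
) -> SyntheticInstance:
    """Sample a hidden truth model and derive profile, panel and labels.

    Link operators are drawn uniformly and resampled (bounded retries)
    until at least one stable state exists.  One stable state is chosen
    as the biological state; the training profile restricts it to a
    random ``obs_fraction`` of nodes and flips each retained observation
    with probability ``flip_prob``.  Drugs are inhibitors of 1 to
    ``max_targets`` random nodes that are not phenotype regulators, so
    treatment effects propagate through the network rather than editing
    the readout directly.  Truth synergy labels come from simulating
    the truth model itself through the perturbation and min-rule
    machinery.
    """
    if not (0 < obs_fraction <= 1):
        raise ValueError("obs_fraction must lie in (0, 1]")
    if not (0 <= flip_prob <= 1):
        raise ValueError("flip_prob must lie in [0, 1]")
    if n_drugs < 2:
        raise ValueError("need at least two drugs for a synergy screen")
    rng = np.random.default_rng(seed)
    if network is None:
        network = generate_network(seed=seed)
    truth, fps = _sample_truth_model(network, rng, max_tries)
    bio_state = fps[int(rng.integers(len(fps)))]

    nodes = list(network.nodes)
    n_obs = max(1, int(round(obs_fraction * len(nodes))))
    observed = sorted(rng.choice(len(nodes), size=n_obs, replace=False).tolist())
    observations = {}
    for i in observed:
        node = nodes[i]
        state = bio_state[node]
        if rng.random() < flip_prob:
            state = 1 - state
        observations[node] = state
    profile = TrainingProfile(observations=observations)

    pheno_regs = {n for pdef in network.phenotype_defs for n, _s in pdef.regulators}
    druggable = [n for n in nodes if n not in pheno_regs]
    if not druggable:
        raise ValueError("no druggable node outside the phenotype regulators")
    panel = []
    for d in range(n_drugs):
        k = int(rng.integers(1, max_targets + 1))
        targets = sorted(
            druggable[i]
            for i in rng.choice(len(druggable), size=min(k, len(druggable)),
                                replace=False)
        )
        panel.append(Drug(name=f"D{d:02d}", targets=targets, effect="inhibit"))

    truth_ensemble = ModelEnsemble(models=[truth], fitnesses=[1.0])
    responses = ensemble_responses(truth_ensemble, panel)
    calls = score_panel(responses, panel)
    truth_labels = {
        frozenset((c.drug_a, c.drug_b)): bool(c.call)
        for c in calls
        if c.defined
    }
    return SyntheticInstance(
        network=network,
        truth_model=truth,
        biological_state=dict(bio_state),
        training_profile=profile,
        panel=panel,
        truth_labels=truth_labels,
        seed=seed,
        obs_fraction=obs_fraction,
        flip_prob=flip_prob,
    )


def two_pathway_toy() -> tuple[LogicalNetwork, BooleanModel, list[Drug]]:
    """A redundant two-pathway survival circuit and its inhibitor panel.

    Two parallel pathways (P1 -> P2, Q1 -> Q2) each suffice to switch on
    the survival effectors V1..V3 that feed Prosurvival; V1 also
    suppresses the death marker A1 feeding Antisurvival.  Blocking one
    pathway changes little — the other sustains the effectors — but
    blocking both collapses the global output, the classic setting for
    a cross-pathway synergy.  The panel holds inhibitors of P1, P2 and
    Q1, so exactly the two cross-pathway pairs are synergistic and the
    within-pathway pair is not.
    """
    lines = [
        ("P1", "P2", 1),
        ("Q1", "Q2", 1),
        ("P2", "V1", 1), ("Q2", "V1", 1),
        ("P2", "V2", 1), ("Q2", "V2", 1),
        ("P2", "V3", 1), ("Q2", "V3", 1),
        ("V1", "A1", -1),
    ]
    nodes = ["P1", "P2", "Q1", "Q2", "V1", "V2", "V3", "A1"]
    pro = PhenotypeDef("Prosurvival", [("V1", 1), ("V2", 1), ("V3", 1)])
    anti = PhenotypeDef("Antisurvival", [("A1", 1)])
    network = LogicalNetwork(
        nodes=nodes,
        edges=[SignedEdge(s, t, sign) for s, t, sign in lines],
        phenotype_defs=[pro, anti],
    )
    model = default_model(network, model_id="two_pathway_toy")
    panel = [
        Drug(name="antiP1", targets=("P1",)),
        Drug(name="antiP2", targets=("P2",)),
        Drug(name="antiQ1", targets=("Q1",)),
    ]
    return network, model, panel
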