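"""Shared fixtures and independent oracles.

The brute-force fixed-point oracle below evaluates every rule as a raw
truth table over all 2^n states with numpy; it shares no code with the
solver it checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from boolsynergy.network_io import (
    AND_NOT,
    OR_NOT,
    BooleanModel,
    LogicalNetwork,
    SignedEdge,
    default_model,
)


def brute_force_fixed_points(model: BooleanModel, clamps=None) -> list[dict]:
    """Exhaustive enumeration of fixed points over all 2^n states."""
    nodes = model.network.nodes
    n = len(nodes)
    clamps = dict(clamps or {})
    idx = {name: i for i, name in enumerate(nodes)}
    m = 2**n
    # bit 0 of the row index encodes the *last* node so that increasing
    # row index is lexicographic in node order
    states = ((np.arange(m)[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(bool)
    ok = np.ones(m, dtype=bool)
    for node, val in clamps.items():
        ok &= states[:, idx[node]] == bool(val)
    for node in nodes:
        if node in clamps:
            continue
        eq = model.equations[node]
        if eq.is_input:
            continue  # x = x holds everywhere
        if eq.activators:
            a = states[:, [idx[r] for r in eq.activators]].any(axis=1)
        if eq.inhibitors:
            i = states[:, [idx[r] for r in eq.inhibitors]].any(axis=1)
        if eq.activators and eq.inhibitors:
            f = (a & ~i) if eq.link_operator == AND_NOT else (a | ~i)
        elif eq.activators:
            f = a
        else:
            f = ~i
        ok &= f == states[:, idx[node]]
    return [
        {name: int(states[r, idx[name]]) for name in nodes}
        for r in np.nonzero(ok)[0]
    ]


def random_model(n_nodes: int, rng: np.random.Generator, p_edge: float = 0.18,
                 model_id: str = "rand") -> BooleanModel:
    """A random signed network with random operators; self-loops and
    dual regulation allowed, so all equation forms get exercised."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = []
    seen = set()
    for s in nodes:
        for t in nodes:
            for sign in (1, -1):
                if rng.random() < p_edge / 2 and (s, t, sign) not in seen:
                    seen.add((s, t, sign))
                    edges.append(SignedEdge(s, t, sign))
    net = LogicalNetwork(nodes=nodes, edges=edges)
    model = default_model(net, model_id=model_id)
    for tgt in model.mutable_targets():
        if rng.random() < 0.5:
            model.equations[tgt] = model.equations[tgt].with_operator(OR_NOT)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
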