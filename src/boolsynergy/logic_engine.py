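"""Exact stable-state (fixed-point) computation and phenotype readout.

A state vector assigns 0/1 to every core node.  A fixed point is a
state mapped to itself by every node's rule; it is the attractor class
used throughout this package (cyclic attractors are out of scope, and a
model may legitimately have none).  Perturbations enter as *clamps*:
a clamped node holds its forced value and its own rule is ignored,
mirroring knock-out / over-expression / pharmacological inhibition.

The multivalued phenotype outputs (pro- and anti-survival, local states
0..3) are read off a fixed point, and the global output state is their
signed combination, an integer in [-3, +3]: -3 means purely
anti-survival activity, +3 purely pro-survival.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .network_io import AND_NOT, OR_NOT, BooleanEquation, BooleanModel, LogicalNetwork

__all__ = [
    "StateVector",
    "PhenotypeDef",
    "GlobalState",
    "ClampSet",
    "ModelResponse",
    "evaluate_equation",
    "fixed_points",
    "phenotype_level",
    "global_state",
    "model_response",
    "survival_phenotype_defs",
]

#: A total assignment node -> {0, 1} over the core nodes.
StateVector = dict


@dataclass(frozen=True)
class PhenotypeDef:
    """A multivalued phenotype output (pro- or anti-survival readout).

    ``regulators`` are (core node, sign) pairs; active positive
    regulators raise the level, active negative regulators lower it,
    and the level saturates at ``max_level`` (fixed at 3, giving local
    states 0, 1, 2, 3).
    """

    name: str
    regulators: tuple
    max_level: int = 3

    def __init__(self, name: str, regulators, max_level: int = 3):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "regulators", tuple(regulators))
        object.__setattr__(self, "max_level", max_level)
        if max_level != 3:
            raise ValueError("phenotype levels are fixed to the 0..3 scale")
        if not self.regulators:
            raise ValueError(f"phenotype {name!r} needs at least one regulator")
        for _node, sign in self.regulators:
            if sign not in (1, -1):
                raise ValueError("phenotype regulator sign must be +1 or -1")


@dataclass(frozen=True)
class GlobalState:
    """Phenotype levels and their signed combination.

    ``value = prosurvival_level - antisurvival_level`` is the global
    output state in [-3, +3].
    """

    prosurvival_level: int
    antisurvival_level: int

    @property
    def value(self) -> int:
        return self.prosurvival_level - self.antisurvival_level


class ClampSet(dict):
    """Forced node states, node -> {0, 1}; validated against a network."""

    def __init__(self, clamps: Optional[Mapping[str, int]] = None,
                 network: Optional[LogicalNetwork] = None):
        super().__init__(clamps or {})
        for node, val in self.items():
            if val not in (0, 1):
                raise ValueError(f"clamp value for {node!r} must be 0 or 1")
            if network is not None and node not in set(network.nodes):
                raise ValueError(f"clamped node {node!r} not in network")


@dataclass(frozen=True)
class ModelResponse:
    """Aggregated global output of one model under one condition.

    ``value`` is the mean global state over all fixed points, or None
    when the model has no fixed point under the given clamps.
    """

    value: Optional[float]
    n_fixed_points: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def evaluate_equation(equation: BooleanEquation, state: Mapping[str, int]) -> int:
    """Evaluate one rule against a (total) state.

    With a = OR over activators and i = OR over inhibitors:
    both sets present -> ``a AND NOT i`` or ``a OR NOT i`` depending on
    the link operator; only activators -> a; only inhibitors -> NOT i;
    a free input keeps its own current state.
    """
    eq = equation
    try:
        if eq.is_input:
            return state[eq.target]
        a = any(state[r] for r in eq.activators) if eq.activators else None
        i = any(state[r] for r in eq.inhibitors) if eq.inhibitors else None
    except KeyError as exc:
        raise KeyError(f"state missing regulator {exc.args[0]!r} of {eq.target!r}")
    if a is not None and i is not None:
        if eq.link_operator == AND_NOT:
            return int(a and not i)
        return int(a or not i)
    if a is not None:
        return int(a)
    return int(not i)


def _partial_eval(eq: BooleanEquation, asg: Mapping[str, int]) -> Optional[int]:
    """Evaluate a rule under a partial assignment; None when undetermined."""
    if eq.is_input:
        return None  # x = x constrains nothing

    def clause(regs: frozenset) -> Optional[int]:
        unknown = False
        for r in regs:
            v = asg.get(r)
            if v == 1:
                return 1
            if v is None:
                unknown = True
        return None if unknown else 0

    a = clause(eq.activators) if eq.activators else None
    i = clause(eq.inhibitors) if eq.inhibitors else None
    if eq.activators and eq.inhibitors:
        if eq.link_operator == AND_NOT:
            if a == 0 or i == 1:
                return 0
            if a == 1 and i == 0:
                return 1
            return None
        if a == 1 or i == 0:
            return 1
        if a == 0 and i == 1:
            return 0
        return None
    if eq.activators:
        return a
    return None if i is None else int(not i)


def _propagate(model: BooleanModel, clamped: frozenset, asg: dict) -> bool:
    """Unit propagation: assign nodes whose rule value is already forced.

    Returns False on a contradiction with an existing assignment.  Only
    unclamped nodes carry the fixed-point constraint x = f(x).
    """
    changed = True
    while changed:
        changed = False
        for node in model.network.nodes:
            if node in clamped:
                continue
            eq = model.equations[node]
            val = _partial_eval(eq, asg)
            if val is None:
                continue
            cur = asg.get(node)
            if cur is None:
                asg[node] = val
                changed = True
            elif cur != val:
                return False
    return True


def _consistent_complete(model: BooleanModel, clamped: frozenset, asg: Mapping[str, int]) -> bool:
    for node in model.network.nodes:
        if node in clamped:
            continue
        if evaluate_equation(model.equations[node], asg) != asg[node]:
            return False
    return True


def fixed_points(
    model: BooleanModel,
    clamps: Optional[Mapping[str, int]] = None,
    *,
    reduce: bool = True,
    node_cap: int = 512,
) -> list[dict]:
    """All fixed points of ``model`` under ``clamps``, exactly.

    Returns every total state s with s(v) = f_v(s) for each unclamped
    node and s(v) equal to the clamp for clamped nodes, sorted
    lexicographically by node order.  The search runs iterated constant
    propagation / reduction followed by backtracking over the remaining
    free variables (``reduce=False`` disables propagation and falls back
    to plain depth-first enumeration; the result is identical).  Free
    input nodes are genuine free variables: both values are explored
    unless the caller clamps them.
    """
    nodes = model.network.nodes
    if len(nodes) > node_cap:
        raise ValueError(f"model has {len(nodes)} nodes, above the cap of {node_cap}")
    clamps = dict(clamps or {})
    for node in clamps:
        if node not in set(nodes):
            raise ValueError(f"clamped node {node!r} not in network")
    clamped = frozenset(clamps)
    results: list[dict] = []

    def search(asg: dict) -> None:
        if reduce and not _propagate(model, clamped, asg):
            return
        if not reduce:
            # cheap local checks: any fully determined rule must agree
            for node in nodes:
                if node in clamped or node not in asg:
                    continue
                val = _partial_eval(model.equations[node], asg)
                if val is not None and val != asg[node]:
                    return
        free = next((n for n in nodes if n not in asg), None)
        if free is None:
            if _consistent_complete(model, clamped, asg):
                results.append(dict(asg))
            return
        for val in (0, 1):
            child = dict(asg)
            child[free] = val
            search(child)

    search(dict(clamps))
    results.sort(key=lambda s: tuple(s[n] for n in nodes))
    return results


def phenotype_level(fp: Mapping[str, int], pdef: PhenotypeDef) -> int:
    """Multivalued level of one phenotype at a fixed point.

    Net count of active regulators (positives minus negatives), clamped
    into [0, max_level]: regulators contribute additively and the level
    saturates at 3.
    """
    net = 0
    for node, sign in pdef.regulators:
        if fp[node]:
            net += sign
    return max(0, min(pdef.max_level, net))


def global_state(fp: Mapping[str, int], pro: PhenotypeDef, anti: PhenotypeDef) -> GlobalState:
    """Global output state at a fixed point: Prosurvival minus Antisurvival."""
    return GlobalState(
        prosurvival_level=phenotype_level(fp, pro),
        antisurvival_level=phenotype_level(fp, anti),
    )


def survival_phenotype_defs(network: LogicalNetwork) -> tuple[PhenotypeDef, PhenotypeDef]:
    """The (Prosurvival, Antisurvival) definitions of a network."""
    return (network.phenotype_def("Prosurvival"), network.phenotype_def("Antisurvival"))


def model_response(
    model: BooleanModel,
    clamps: Optional[Mapping[str, int]] = None,
) -> ModelResponse:
    """Mean global state over all fixed points under ``clamps``.

    The response is undefined (value None) when no fixed point exists;
    the fixed-point count is always reported so callers can apply a
    quorum.
    """
    pro, anti = survival_phenotype_defs(model.network)
    fps = fixed_points(model, clamps)
    if not fps:
        return ModelResponse(value=None, n_fixed_points=0)
    values = [global_state(fp, pro, anti).value for fp in fps]
    return ModelResponse(value=sum(values) / len(values), n_fixed_points=len(fps))
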