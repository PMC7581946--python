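"""Signed-network I/O and default Boolean model construction.

A prior-knowledge network is a signed directed graph in SIF (simple
interaction file) format: one interaction per line, ``source relation
target``.  Activating relations map to sign +1, inhibiting relations to
sign -1.  From the topology alone a default Boolean model is built with
the standard rule template

    X = (activator_1 OR ... OR activator_m) AND NOT (inhibitor_1 OR ...)

one equation per core node.  The link operator joining the activator
clause and the negated inhibitor clause (``AND NOT`` vs ``OR NOT``) is
the only degree of freedom later optimization touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SignedEdge",
    "LogicalNetwork",
    "BooleanEquation",
    "BooleanModel",
    "SifFormatError",
    "read_sif",
    "write_sif",
    "default_model",
    "read_node_annotations",
    "read_phenotype_defs",
    "AND_NOT",
    "OR_NOT",
]

#: Link-operator constants.  AND_NOT is the biologically conservative
#: default: any active inhibitor silences the node.
AND_NOT = "AND_NOT"
OR_NOT = "OR_NOT"

_ACTIVATE_TOKENS = {"activate", "->", "1"}
_INHIBIT_TOKENS = {"inhibit", "-|", "-1"}


class SifFormatError(ValueError):
    """Raised when a SIF file cannot be interpreted as a signed network."""


@dataclass(frozen=True, order=True)
class SignedEdge:
    """A signed directed interaction ``source -> target``.

    ``sign`` is +1 for activation and -1 for inhibition.
    """

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")
        if not self.source or not self.target:
            raise ValueError("edge endpoints must be non-empty strings")


@dataclass
class LogicalNetwork:
    """A signed directed graph plus phenotype-output definitions.

    ``nodes`` are the core (dynamical) nodes in first-appearance order.
    Phenotype outputs (pro-/anti-survival readouts) are *not* core nodes;
    they are virtual multivalued sinks described by ``phenotype_defs``
    (see :mod:`boolsynergy.logic_engine`) whose regulators must be core
    nodes.  ``node_annotation`` optionally maps a node to its HGNC gene
    symbols and a module label (family nodes carry an ``_f`` suffix,
    complexes ``_c``).
    """

    nodes: list[str]
    edges: list[SignedEdge]
    phenotype_defs: list = field(default_factory=list)
    node_annotation: Optional[dict[str, tuple[list[str], str]]] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        for e in self.edges:
            if e.source not in node_set or e.target not in node_set:
                raise ValueError(f"edge {e} references unknown node")
        if len({(e.source, e.target, e.sign) for e in self.edges}) != len(self.edges):
            raise ValueError("duplicate signed edges")
        for pdef in self.phenotype_defs:
            for reg, _sign in pdef.regulators:
                if reg not in node_set:
                    raise ValueError(
                        f"phenotype {pdef.name!r} regulator {reg!r} not in network"
                    )

    def regulators_of(self, node: str) -> tuple[frozenset[str], frozenset[str]]:
        """Return (activators, inhibitors) of ``node``."""
        acts = frozenset(e.source for e in self.edges if e.target == node and e.sign == 1)
        inhs = frozenset(e.source for e in self.edges if e.target == node and e.sign == -1)
        return acts, inhs

    def phenotype_def(self, name: str):
        for pdef in self.phenotype_defs:
            if pdef.name == name:
                return pdef
        raise KeyError(f"no phenotype definition named {name!r}")


@dataclass(frozen=True)
class BooleanEquation:
    """One logical rule: target state from activator and inhibitor sets.

    The same source may appear in both sets (dual regulation); it then
    contributes to both the activator and the inhibitor clause.  The
    link operator is meaningful only when both sets are non-empty; an
    equation with both sets empty marks a free input node.
    """

    target: str
    activators: frozenset[str]
    inhibitors: frozenset[str]
    link_operator: str = AND_NOT

    def __post_init__(self) -> None:
        if self.link_operator not in (AND_NOT, OR_NOT):
            raise ValueError(f"unknown link operator {self.link_operator!r}")

    @property
    def is_input(self) -> bool:
        return not self.activators and not self.inhibitors

    @property
    def is_mutable(self) -> bool:
        """True when the link operator actually affects the truth table."""
        return bool(self.activators) and bool(self.inhibitors)

    def with_operator(self, op: str) -> "BooleanEquation":
        return replace(self, link_operator=op)

    def toggled(self) -> "BooleanEquation":
        return self.with_operator(OR_NOT if self.link_operator == AND_NOT else AND_NOT)


@dataclass
class BooleanModel:
    """A full rule assignment over a network's core nodes.

    Models sharing a network differ only in their link-operator
    assignments; that is the ensemble notion used throughout.
    """

    network: LogicalNetwork
    equations: dict[str, BooleanEquation]
    model_id: str = "model"

    def __post_init__(self) -> None:
        if set(self.equations) != set(self.network.nodes):
            raise ValueError("equations must cover exactly the core nodes")

    def mutable_targets(self) -> list[str]:
        """Targets whose link operator is free, in node order."""
        return [n for n in self.network.nodes if self.equations[n].is_mutable]

    def operator_signature(self) -> tuple[str, ...]:
        return tuple(self.equations[n].link_operator for n in self.mutable_targets())

    def copy(self, model_id: Optional[str] = None) -> "BooleanModel":
        return BooleanModel(
            network=self.network,
            equations=dict(self.equations),
            model_id=self.model_id if model_id is None else model_id,
        )


def _parse_sign(token: str, lineno: int) -> int:
    if token in _ACTIVATE_TOKENS:
        return 1
    if token in _INHIBIT_TOKENS:
        return -1
    raise SifFormatError(
        f"line {lineno}: unknown relation token {token!r} "
        f"(expected one of {sorted(_ACTIVATE_TOKENS | _INHIBIT_TOKENS)})"
    )


def read_sif(path: str | Path) -> LogicalNetwork:
    """Read a signed network from a SIF file.

    Accepts tab- or whitespace-separated ``source relation target`` rows;
    ``#`` starts a comment.  Relation tokens: ``activate``/``->``/``1``
    activate, ``inhibit``/``-|``/``-1`` inhibit; anything else is a
    format error naming the line.  Node order is first-appearance order
    and repeated identical triples collapse to a single edge.
    """
    path = Path(path)
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    edges: list[SignedEdge] = []
    seen_edges: set[tuple[str, str, int]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise SifFormatError(
                    f"line {lineno}: expected 3 fields, got {len(fields)}: {line!r}"
                )
            src, rel, tgt = fields
            sign = _parse_sign(rel, lineno)
            for n in (src, tgt):
                if n not in seen_nodes:
                    seen_nodes.add(n)
                    nodes.append(n)
            key = (src, tgt, sign)
            if key not in seen_edges:
                seen_edges.add(key)
                edges.append(SignedEdge(src, tgt, sign))
    if not edges:
        raise SifFormatError(f"{path}: no interactions found")
    return LogicalNetwork(nodes=nodes, edges=edges)


def write_sif(network: LogicalNetwork, path: str | Path) -> None:
    """Write the edge list as canonical SIF (``->`` / ``-|``, sorted rows)."""
    if not network.edges:
        raise ValueError("refusing to write a network with no edges")
    path = Path(path)
    lines = []
    for e in sorted(network.edges):
        token = "->" if e.sign == 1 else "-|"
        lines.append(f"{e.source}\t{token}\t{e.target}")
    path.write_text("\n".join(lines) + "\n")


def default_model(network: LogicalNetwork, model_id: str = "default") -> BooleanModel:
    """Instantiate the baseline model from topology.

    Every node with at least one activator and one inhibitor gets the
    AND_NOT operator (active iff some activator is active and no
    inhibitor is); nodes with only one kind of regulator need no
    operator; regulator-free nodes become free inputs.
    """
    equations = {}
    for node in network.nodes:
        acts, inhs = network.regulators_of(node)
        equations[node] = BooleanEquation(
            target=node, activators=acts, inhibitors=inhs, link_operator=AND_NOT
        )
    return BooleanModel(network=network, equations=equations, model_id=model_id)


def read_node_annotations(path: str | Path) -> dict[str, tuple[list[str], str]]:
    """Read a node-annotation TSV: columns node, gene_symbols, module.

    ``gene_symbols`` is a comma-separated list of HGNC symbols.  A header
    row is detected by the literal column name ``node``.
    """
    annotation: dict[str, tuple[list[str], str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() == "node":
            continue
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated columns")
        node, symbols, module = fields[0], fields[1], fields[2]
        genes = [s.strip() for s in symbols.split(",") if s.strip()]
        annotation[node] = (genes, module)
    return annotation


def read_phenotype_defs(path: str | Path) -> list:
    """Read phenotype definitions from a TSV.

    Columns: phenotype (Prosurvival|Antisurvival), regulator_node, sign
    (+1/-1 or 1/-1).  Returns one PhenotypeDef per phenotype name.
    """
    from .logic_engine import PhenotypeDef  # circular at module level

    regs: dict[str, list[tuple[str, int]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() == "phenotype":
            continue
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated columns")
        name, node, sign_s = fields[0], fields[1], fields[2]
        sign = int(sign_s.lstrip("+"))
        if sign not in (1, -1):
            raise ValueError(f"line {lineno}: sign must be +1 or -1")
        if name not in ("Prosurvival", "Antisurvival"):
            raise ValueError(f"line {lineno}: unknown phenotype {name!r}")
        regs.setdefault(name, []).append((node, sign))
    return [PhenotypeDef(name=name, regulators=r) for name, r in regs.items()]
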