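"""Drugs as node clamps; treatment conditions; ensemble response tables.

A drug is characterized by the nodes it targets: an inhibitor clamps
its targets to 0, an activator to 1, for the whole simulation (hard,
complete target engagement; graded inhibition is out of scope).  The
condition grid for a screen is the untreated baseline, every single
drug, and every unordered pair.  Responses are per-model mean global
states, aggregated over the ensemble; a model with no fixed point under
a condition contributes nothing and is counted as NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .ga_optimizer import ModelEnsemble
from .logic_engine import ClampSet, model_response
from .network_io import LogicalNetwork

__all__ = [
    "Drug",
    "PerturbationCondition",
    "ResponseRow",
    "ResponseTable",
    "ClampConflictError",
    "condition_clamps",
    "enumerate_conditions",
    "ensemble_responses",
    "read_drug_panel",
]

UNTREATED_ID = "untreated"


class ClampConflictError(ValueError):
    """Two drugs in one condition force the same node to different values."""


@dataclass(frozen=True)
class Drug:
    """A perturbagen mapped to model nodes via target profiling."""

    name: str
    targets: tuple[str, ...]
    effect: str = "inhibit"

    def __init__(self, name: str, targets: Iterable[str], effect: str = "inhibit"):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "targets", tuple(targets))
        object.__setattr__(self, "effect", effect)
        if not self.name:
            raise ValueError("drug needs a name")
        if not self.targets:
            raise ValueError(f"drug {name!r} needs at least one target")
        if self.effect not in ("inhibit", "activate"):
            raise ValueError("effect must be 'inhibit' or 'activate'")

    @property
    def clamp_value(self) -> int:
        return 0 if self.effect == "inhibit" else 1

    def validate_against(self, network: LogicalNetwork) -> None:
        node_set = set(network.nodes)
        for t in self.targets:
            if t not in node_set:
                raise ValueError(f"drug {self.name!r} target {t!r} not in network")


@dataclass(frozen=True)
class PerturbationCondition:
    """Untreated (0 drugs), single (1) or pairwise (2) treatment."""

    drugs: tuple[Drug, ...]

    def __init__(self, drugs: Iterable[Drug] = ()):
        ordered = tuple(sorted(drugs, key=lambda d: d.name))
        object.__setattr__(self, "drugs", ordered)
        names = [d.name for d in ordered]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug in condition")
        if len(ordered) > 2:
            raise ValueError("conditions hold at most two drugs")
        condition_clamps(self)  # raises ClampConflictError on conflict

    @property
    def condition_id(self) -> str:
        if not self.drugs:
            return UNTREATED_ID
        return "+".join(d.name for d in self.drugs)


def condition_clamps(condition: PerturbationCondition) -> ClampSet:
    """Union of the drugs' target clamps (inhibit -> 0, activate -> 1)."""
    clamps: dict[str, int] = {}
    for drug in condition.drugs:
        for node in drug.targets:
            val = drug.clamp_value
            if node in clamps and clamps[node] != val:
                raise ClampConflictError(
                    f"condition {'+'.join(d.name for d in condition.drugs)!r}: "
                    f"conflicting clamps on node {node!r}"
                )
            clamps[node] = val
    return ClampSet(clamps)


def pair_id(a: str, b: str) -> str:
    """Canonical condition id of an unordered drug pair."""
    x, y = sorted((a, b))
    return f"{x}+{y}"


def enumerate_conditions(panel: Sequence[Drug]) -> list[PerturbationCondition]:
    """Untreated + all singles + all unordered pairs.

    For n drugs that is 1 + n + n(n-1)/2 conditions (18 drugs give 153
    pairs, 19 give 171).  Singles follow panel order; pairs are sorted
    lexicographically by their name pair.
    """
    names = [d.name for d in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate drug names in panel")
    if len(panel) < 2:
        raise ValueError("a screen panel needs at least two drugs")
    conditions = [PerturbationCondition(())]
    conditions.extend(PerturbationCondition((d,)) for d in panel)
    pairs = sorted(
        ((a, b) for i, a in enumerate(panel) for b in panel[i + 1:]),
        key=lambda ab: tuple(sorted((ab[0].name, ab[1].name))),
    )
    conditions.extend(PerturbationCondition(p) for p in pairs)
    return conditions


@dataclass(frozen=True)
class ResponseRow:
    """One condition's ensemble response."""

    condition_id: str
    mean_response: Optional[float]
    per_model: Mapping[str, Optional[float]]
    n_na: int

    @property
    def n_defined(self) -> int:
        return len(self.per_model) - self.n_na


@dataclass
class ResponseTable:
    """Condition id -> :class:`ResponseRow` for a whole screen."""

    rows: dict[str, ResponseRow]

    def __getitem__(self, condition_id: str) -> ResponseRow:
        return self.rows[condition_id]

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self.rows

    def write_tsv(self, path: str | Path) -> None:
        lines = ["condition\tmean_response\tn_models_defined\tn_models_na"]
        for cid, row in self.rows.items():
            mean = "NA" if row.mean_response is None else f"{row.mean_response:.6g}"
            lines.append(f"{cid}\t{mean}\t{row.n_defined}\t{row.n_na}")
        Path(path).write_text("\n".join(lines) + "\n")


def ensemble_responses(
    ensemble: ModelEnsemble,
    panel: Sequence[Drug],
    conditions: Optional[Sequence[PerturbationCondition]] = None,
) -> ResponseTable:
    """Simulate every condition against every ensemble member.

    The row mean averages over defined (non-NA) model responses only and
    is None when every member lacks a fixed point under the condition.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    if conditions is None:
        conditions = enumerate_conditions(panel)
    for drug in panel:
        drug.validate_against(ensemble.models[0].network)
    rows: dict[str, ResponseRow] = {}
    for cond in conditions:
        clamps = condition_clamps(cond)
        per_model: dict[str, Optional[float]] = {}
        for model in ensemble.models:
            resp = model_response(model, clamps)
            per_model[model.model_id] = resp.value
        defined = [v for v in per_model.values() if v is not None]
        mean = sum(defined) / len(defined) if defined else None
        rows[cond.condition_id] = ResponseRow(
            condition_id=cond.condition_id,
            mean_response=mean,
            per_model=per_model,
            n_na=len(per_model) - len(defined),
        )
    return ResponseTable(rows=rows)


def read_drug_panel(path: str | Path) -> list[Drug]:
    """Read a panel TSV: columns drug, effect (inhibit|activate), targets.

    ``targets`` is a comma-separated list of node names.
    """
    drugs: list[Drug] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() == "drug":
            continue
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected columns drug, effect, targets")
        targets = [t.strip() for t in fields[2].split(",") if t.strip()]
        drugs.append(Drug(name=fields[0], targets=targets, effect=fields[1]))
    return drugs
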