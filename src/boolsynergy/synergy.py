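"""Min-rule (highest-single-agent style) synergy scoring of drug pairs.

A pair is synergistic for one model when the combination's global
output state is *strictly* smaller than the minimum of the two single
treatments — the combination kills viability beyond the better single
agent; ties are non-synergistic.  Two ensemble views are kept:

* ``vote_fraction`` — the fraction of models individually calling the
  pair synergistic (the per-model rule, robust to attractor-count
  artifacts); the binary call thresholds this fraction.
* ``excess`` — the mean over models of min(single_a, single_b) minus
  the pair response; a continuous score suited to ROC ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .perturbation import Drug, ResponseTable, UNTREATED_ID, pair_id

__all__ = [
    "SynergyCall",
    "score_pair",
    "score_panel",
    "read_synergy_labels",
    "write_calls_tsv",
]

DEFAULT_CALL_THRESHOLD = 0.5


@dataclass(frozen=True)
class SynergyCall:
    """One drug pair's synergy verdict.

    ``defined`` is False (and score fields None) when no model had a
    fixed point under all three of single-a, single-b and the pair.
    """

    drug_a: str
    drug_b: str
    excess: Optional[float]
    vote_fraction: Optional[float]
    call: Optional[bool]
    observed_label: Optional[bool] = None
    defined: bool = True


def score_pair(
    responses: ResponseTable,
    a: str,
    b: str,
    call_threshold: float = DEFAULT_CALL_THRESHOLD,
) -> SynergyCall:
    """Score one unordered pair by the per-model min rule.

    Only models with defined responses under both singles and the pair
    contribute.  ``vote_fraction`` is the mean of the per-model strict
    comparisons; ``excess`` the mean shortfall of the pair below the
    better single.
    """
    drug_a, drug_b = sorted((a, b))
    for cid in (UNTREATED_ID, drug_a, drug_b, pair_id(drug_a, drug_b)):
        if cid not in responses:
            raise KeyError(f"response table is missing condition {cid!r}")
    row_a = responses[drug_a]
    row_b = responses[drug_b]
    row_ab = responses[pair_id(drug_a, drug_b)]
    votes: list[int] = []
    excesses: list[float] = []
    for model_id, ra in row_a.per_model.items():
        rb = row_b.per_model.get(model_id)
        rab = row_ab.per_model.get(model_id)
        if ra is None or rb is None or rab is None:
            continue
        single_min = min(ra, rb)
        votes.append(int(rab < single_min))
        excesses.append(single_min - rab)
    if not votes:
        return SynergyCall(drug_a, drug_b, excess=None, vote_fraction=None,
                           call=None, defined=False)
    vote_fraction = sum(votes) / len(votes)
    return SynergyCall(
        drug_a=drug_a,
        drug_b=drug_b,
        excess=sum(excesses) / len(excesses),
        vote_fraction=vote_fraction,
        call=vote_fraction > call_threshold,
    )


def score_panel(
    responses: ResponseTable,
    panel: Sequence[Drug],
    labels: Optional[Mapping[frozenset, bool]] = None,
    call_threshold: float = DEFAULT_CALL_THRESHOLD,
) -> list[SynergyCall]:
    """One :class:`SynergyCall` per unordered pair, in canonical pair order.

    ``labels`` maps frozenset({drug_a, drug_b}) to the observed synergy
    label; a label naming a drug outside the panel is an error.
    """
    names = sorted(d.name for d in panel)
    if labels:
        known = set(names)
        for key in labels:
            unknown = set(key) - known
            if unknown:
                raise ValueError(f"synergy label names unknown drugs {sorted(unknown)}")
    calls = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            call = score_pair(responses, na, nb, call_threshold)
            if labels is not None and frozenset((na, nb)) in labels:
                call = SynergyCall(
                    drug_a=call.drug_a,
                    drug_b=call.drug_b,
                    excess=call.excess,
                    vote_fraction=call.vote_fraction,
                    call=call.call,
                    observed_label=labels[frozenset((na, nb))],
                    defined=call.defined,
                )
            calls.append(call)
    return calls


def read_synergy_labels(path: str | Path) -> dict[frozenset, bool]:
    """Read observed labels TSV: columns drug_a, drug_b, label (0|1)."""
    labels: dict[frozenset, bool] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() == "drug_a":
            continue
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected columns drug_a, drug_b, label")
        labels[frozenset((fields[0], fields[1]))] = bool(int(fields[2]))
    return labels


def write_calls_tsv(calls: Sequence[SynergyCall], path: str | Path) -> None:
    lines = ["drug_a\tdrug_b\texcess\tvote_fraction\tcall\tobserved_label"]
    for c in calls:
        def fmt(v):
            return "NA" if v is None else (f"{v:.6g}" if isinstance(v, float) else str(int(v)))
        lines.append("\t".join([
            c.drug_a, c.drug_b, fmt(c.excess), fmt(c.vote_fraction),
            fmt(c.call), fmt(c.observed_label),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
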