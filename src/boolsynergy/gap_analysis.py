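"""Middle-out gap analysis: where genome-wide signal outruns the model.

Given per-condition lists of affected genes (already thresholded by
upstream tools), gene-set overrepresentation flags the pathways active
in each condition; comparing those against the pathways a curated model
already covers yields the *gaps* — pathways significant somewhere but
absent from the model, i.e., candidate modules for bottom-up extension.

Enrichment is the one-sided hypergeometric (Fisher) test with BH-FDR
correction across sets; adjusted p < 0.05 counts as significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .evaluation_stats import bh_adjust

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "hypergeometric_enrich",
    "overlap_counts",
    "coverage_matrix",
    "model_covered_sets",
    "read_gmt",
    "read_gene_list",
]

DEFAULT_ALPHA = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets over a gene universe.

    When no universe is given it defaults to the union of the sets.
    Sets are restricted to the universe at construction.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("collection has no gene sets")
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}
        if not self.universe:
            u: set[str] = set()
            for genes in self.sets.values():
                u |= genes
            self.universe = frozenset(u)
        else:
            self.universe = frozenset(self.universe)
            self.sets = {n: g & self.universe for n, g in self.sets.items()}


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    list_size: int
    pvalue: float
    adj_pvalue: float
    significant: bool


def hypergeometric_enrich(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentRow]:
    """Overrepresentation of ``gene_list`` in each set of the collection.

    Upper-tail hypergeometric p = P(X >= k) with N = |universe|,
    K = |set|, n = |list|, k = |overlap|; BH adjustment across sets;
    significance at adjusted p < ``alpha``.  Genes outside the universe
    are ignored (they cannot contribute to any overlap).
    """
    genes = frozenset(gene_list) & collection.universe
    if not genes:
        raise ValueError("gene list is empty (or disjoint from the universe)")
    N = len(collection.universe)
    n = len(genes)
    names = sorted(collection.sets)
    pvals = []
    overlaps = []
    for name in names:
        K = len(collection.sets[name])
        k = len(genes & collection.sets[name])
        overlaps.append(k)
        # P(X >= k); sf(k-1) is exact for the discrete tail
        pvals.append(float(_sps.hypergeom.sf(k - 1, N, K, n)))
    adj = bh_adjust(pvals)
    return [
        EnrichmentRow(
            set_name=name,
            overlap=k,
            set_size=len(collection.sets[name]),
            list_size=n,
            pvalue=p,
            adj_pvalue=a,
            significant=a < alpha,
        )
        for name, k, p, a in zip(names, overlaps, pvals, adj)
    ]


def overlap_counts(lists: Mapping[str, Iterable[str]]) -> dict[tuple, int]:
    """Venn-region counts for 2-4 named gene lists.

    Keys are sorted tuples of list names; the value counts genes that
    belong to exactly those lists.  Counts over all 2^k - 1 regions sum
    to the size of the union.
    """
    if not (2 <= len(lists) <= 4):
        raise ValueError("overlap_counts handles 2 to 4 lists")
    sets = {name: frozenset(genes) for name, genes in lists.items()}
    for name, s in sets.items():
        if not s:
            raise ValueError(f"gene list {name!r} is empty")
    union: set[str] = set()
    for s in sets.values():
        union |= s
    names = sorted(sets)
    counts: dict[tuple, int] = {}
    # all non-empty name subsets, even when the region count is zero
    for mask in range(1, 2 ** len(names)):
        region = tuple(n for i, n in enumerate(names) if mask >> i & 1)
        counts[region] = 0
    for gene in union:
        region = tuple(n for n in names if gene in sets[n])
        counts[region] += 1
    return counts


def model_covered_sets(
    node_annotation: Mapping[str, tuple[list[str], str]],
    collection: GeneSetCollection,
    min_overlap: int = 2,
) -> frozenset[str]:
    """Gene sets a model covers through its nodes' gene symbols.

    A set counts as covered when at least ``min_overlap`` of the model's
    genes are members.  Requires node annotations; raise otherwise so a
    missing annotation file fails loudly rather than reporting every
    set as a gap.
    """
    if not node_annotation:
        raise ValueError("model coverage needs node annotations with gene symbols")
    model_genes: set[str] = set()
    for genes, _module in node_annotation.values():
        model_genes.update(genes)
    return frozenset(
        name
        for name, members in collection.sets.items()
        if len(model_genes & members) >= min_overlap
    )


def coverage_matrix(
    enrichments: Mapping[str, Sequence[EnrichmentRow]],
    model_sets: Iterable[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Presence/absence matrix of pathways across conditions and the model.

    Rows are sets significant in at least one condition or covered by
    the model; columns are the conditions plus a final ``model`` column.
    Returns (matrix, gap list) where a gap is a row significant
    somewhere with a 0 in the model column.
    """
    model_sets = frozenset(model_sets)
    if len(set(enrichments)) != len(enrichments):
        raise ValueError("condition names must be unique")
    sig_by_cond = {
        cond: frozenset(r.set_name for r in rows if r.significant)
        for cond, rows in enrichments.items()
    }
    all_sig: set[str] = set()
    for s in sig_by_cond.values():
        all_sig |= s
    row_names = sorted(all_sig | model_sets)
    conds = list(enrichments)
    data = {
        cond: [int(name in sig_by_cond[cond]) for name in row_names]
        for cond in conds
    }
    data["model"] = [int(name in model_sets) for name in row_names]
    matrix = pd.DataFrame(data, index=row_names)
    gaps = sorted(all_sig - model_sets)
    return matrix, gaps


def read_gmt(path: str | Path, universe: Optional[Iterable[str]] = None) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: GMT rows need name, description, >=1 gene")
        name = fields[0]
        if name in sets:
            raise ValueError(f"line {lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets, universe=frozenset(universe or ()))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a gene list: one symbol per line, ``#`` comments ignored."""
    genes = []
    for raw in Path(path).read_text().splitlines():
        g = raw.strip()
        if g and not g.startswith("#"):
            genes.append(g)
    return genes
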