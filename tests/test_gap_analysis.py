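import itertools
import math

import numpy as np
import pytest

from boolsynergy.gap_analysis import (
    GeneSetCollection,
    coverage_matrix,
    hypergeometric_enrich,
    model_covered_sets,
    overlap_counts,
    read_gene_list,
    read_gmt,
)


def genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestHypergeometricEnrich:
    def test_zero_overlap_gives_p_one(self):
        coll = GeneSetCollection(sets={"S": frozenset(genes("a", 5))},
                                 universe=frozenset(genes("a", 5) + genes("b", 5)))
        rows = hypergeometric_enrich(genes("b", 3), coll)
        assert rows[0].overlap == 0 and rows[0].pvalue == pytest.approx(1.0)

    def test_full_overlap_matches_exhaustive_enumeration(self):
        """P of drawing the whole 5-gene set in 5 of 10 draws = 1/C(10,5)."""
        universe = genes("g", 10)
        target = universe[:5]
        coll = GeneSetCollection(sets={"S": frozenset(target)},
                                 universe=frozenset(universe))
        rows = hypergeometric_enrich(target, coll)
        # independent oracle: enumerate all C(10,5) = 252 possible lists
        hits = sum(1 for draw in itertools.combinations(universe, 5)
                   if len(set(draw) & set(target)) >= 5)
        assert hits == 1
        assert rows[0].pvalue == pytest.approx(1 / 252)

    def test_tail_enumeration_on_partial_overlap(self):
        """p = P(X >= k) checked against literal draw enumeration."""
        universe = genes("g", 12)
        target = set(universe[:6])
        gene_list = universe[:4] + universe[8:10]  # overlap 4, size 6
        coll = GeneSetCollection(sets={"S": frozenset(target)},
                                 universe=frozenset(universe))
        rows = hypergeometric_enrich(gene_list, coll)
        k = rows[0].overlap
        assert k == 4
        total = hits = 0
        for draw in itertools.combinations(universe, 6):
            total += 1
            hits += len(set(draw) & target) >= k
        assert rows[0].pvalue == pytest.approx(hits / total)

    def test_monte_carlo_oracle(self):
        """Enrichment p agrees with resampled random gene lists."""
        rng = np.random.default_rng(99)
        N, K, n = 60, 18, 12
        universe = genes("g", N)
        target = set(universe[:K])
        gene_list = universe[:6] + universe[30:36]  # overlap 6
        coll = GeneSetCollection(sets={"S": frozenset(target)},
                                 universe=frozenset(universe))
        p = hypergeometric_enrich(gene_list, coll)[0].pvalue
        reps = 100_000
        ranks = np.argsort(rng.random((reps, N)), axis=1)[:, :n]
        overlaps = (ranks < K).sum(axis=1)
        mc = float((overlaps >= 6).mean())
        se = math.sqrt(p * (1 - p) / reps)
        assert abs(p - mc) < 3 * se + 1e-9

    def test_p_monotone_decreasing_in_overlap(self):
        universe = genes("g", 40)
        target = set(universe[:10])
        coll = GeneSetCollection(sets={"S": frozenset(target)},
                                 universe=frozenset(universe))
        pvals = []
        for k in range(0, 6):
            gene_list = universe[:k] + universe[20: 20 + (6 - k)]
            pvals.append(hypergeometric_enrich(gene_list, coll)[0].pvalue)
        assert all(b < a for a, b in zip(pvals, pvals[1:]))

    def test_bh_and_significance_across_sets(self):
        universe = genes("g", 30)
        coll = GeneSetCollection(
            sets={"hit": frozenset(universe[:8]),
                  "miss": frozenset(universe[20:28])},
            universe=frozenset(universe),
        )
        rows = {r.set_name: r for r in hypergeometric_enrich(universe[:8], coll)}
        assert rows["hit"].significant and not rows["miss"].significant
        assert rows["hit"].adj_pvalue >= rows["hit"].pvalue

    def test_empty_inputs_rejected(self):
        coll = GeneSetCollection(sets={"S": frozenset(genes("a", 3))})
        with pytest.raises(ValueError):
            hypergeometric_enrich([], coll)
        with pytest.raises(ValueError):
            hypergeometric_enrich(["zz_not_in_universe"], coll)
        with pytest.raises(ValueError):
            GeneSetCollection(sets={})


class TestOverlapCounts:
    def test_identical_lists(self):
        g = genes("a", 7)
        counts = overlap_counts({"x": g, "y": g})
        assert counts[("x", "y")] == 7
        assert counts[("x",)] == 0 and counts[("y",)] == 0

    def test_disjoint_lists(self):
        counts = overlap_counts({"x": genes("a", 3), "y": genes("b", 4)})
        assert counts[("x", "y")] == 0
        assert counts[("x",)] == 3 and counts[("y",)] == 4

    def test_four_random_lists_against_tabulation(self, rng):
        pool = genes("g", 40)
        lists = {
            name: [pool[i] for i in rng.choice(40, size=15, replace=False)]
            for name in ("a", "b", "c", "d")
        }
        counts = overlap_counts(lists)
        assert len(counts) == 2**4 - 1
        union = set().union(*(set(v) for v in lists.values()))
        assert sum(counts.values()) == len(union)
        for gene in union:
            region = tuple(n for n in sorted(lists) if gene in set(lists[n]))
            assert counts[region] >= 1

    def test_list_count_bounds(self):
        with pytest.raises(ValueError):
            overlap_counts({"x": genes("a", 2)})


class TestCoverageMatrix:
    def rows(self, names, sig):
        from boolsynergy.gap_analysis import EnrichmentRow
        return [EnrichmentRow(set_name=n, overlap=1, set_size=5, list_size=5,
                              pvalue=0.01, adj_pvalue=0.01,
                              significant=(n in sig)) for n in names]

    def test_everywhere_significant_and_covered_is_all_ones(self):
        enr = {"c1": self.rows(["S"], {"S"}), "c2": self.rows(["S"], {"S"})}
        matrix, gaps = coverage_matrix(enr, model_sets={"S"})
        assert matrix.loc["S"].tolist() == [1, 1, 1]
        assert gaps == []

    def test_planted_gaps_are_reported_exactly(self):
        """Three pathways significant somewhere but missing from the model."""
        names = ["covered", "gapA", "gapB", "gapC", "noise"]
        enr = {
            "c1": self.rows(names, {"covered", "gapA", "gapB"}),
            "c2": self.rows(names, {"gapC"}),
        }
        matrix, gaps = coverage_matrix(enr, model_sets={"covered", "extra"})
        assert gaps == ["gapA", "gapB", "gapC"]
        assert matrix.loc["gapA", "model"] == 0
        assert matrix.loc["covered", "model"] == 1
        assert "noise" not in matrix.index.tolist() or \
            matrix.loc["noise"].sum() == 0

    def test_gap_list_empty_when_model_covers_everything(self):
        enr = {"c1": self.rows(["S", "T"], {"S", "T"})}
        _matrix, gaps = coverage_matrix(enr, model_sets={"S", "T", "U"})
        assert gaps == []


class TestModelCoverage:
    def test_min_overlap_rule(self):
        coll = GeneSetCollection(sets={
            "two_hits": frozenset({"KRAS", "BRAF", "zz1"}),
            "one_hit": frozenset({"TP53", "zz2", "zz3"}),
        })
        ann = {"KRAS": (["KRAS"], "m1"), "BRAF_c": (["BRAF", "TP53"], "m2")}
        covered = model_covered_sets(ann, coll, min_overlap=2)
        assert covered == {"two_hits"}

    def test_missing_annotation_fails_loudly(self):
        coll = GeneSetCollection(sets={"S": frozenset({"A", "B"})})
        with pytest.raises(ValueError, match="annotation"):
            model_covered_sets({}, coll)


class TestFormats:
    def test_gmt_round_trip_fields(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("WNT\tdesc\tWNT1\tCTNNB1\nMAPK\tna\tKRAS\tBRAF\tMAP2K1\n")
        coll = read_gmt(p)
        assert coll.sets["MAPK"] == {"KRAS", "BRAF", "MAP2K1"}
        assert "WNT1" in coll.universe

    def test_gmt_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S\td\tA\nS\td\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_gene_list_reader(self, tmp_path):
        p = tmp_path / "list.txt"
        p.write_text("# condition genes\nKRAS\n\nTP53\n")
        assert read_gene_list(p) == ["KRAS", "TP53"]
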