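from __future__ import annotations

import random

import pytest

from pathcondense.condense import (
    condense_collection,
    exclude_small,
    merge_decision,
)
from pathcondense.errors import InvalidUniverseError, ValidationError
from pathcondense.model import PathwayCollection
from pathcondense.synth import SynthConfig, generate_collection

from .conftest import P, hypergeom_tail


def G(n: int, start: int = 1) -> list[str]:
    return [f"g{i}" for i in range(start, start + n)]


class TestMergeDecision:
    def test_one_gene_difference_flags_criterion_2(self):
        a, b = P("A", *G(10)), P("B", *G(11))
        d = merge_decision(a, b, universe_size=100)
        assert d.c2_differ_by_one and d.mergeable
        # overlap 10/11 also clears the 90% bar, so precedence labels it c1
        assert d.criterion == "c1"

    def test_one_gene_difference_below_90pct_is_labelled_c2(self):
        d = merge_decision(P("A", *G(5)), P("B", *G(6)), universe_size=100)
        assert d.c2_differ_by_one and d.criterion == "c2"

    def test_small_subset_triggers_criterion_3(self):
        d = merge_decision(P("A", "g1", "g2"), P("B", *G(20)), universe_size=100)
        assert d.c3_small_subset and d.mergeable
        assert not d.c1_overlap_gt_90 and not d.c2_differ_by_one

    def test_significant_half_overlap_triggers_criterion_4(self):
        # 10-gene pathways sharing 8 genes in a 1,000-gene universe:
        # overlap 8/12 > 0.5 and the exact tail p is far below 0.05.
        shared, a_only, b_only = G(8), G(2, 100), G(2, 200)
        a, b = P("A", *shared, *a_only), P("B", *shared, *b_only)
        d = merge_decision(a, b, universe_size=1000)
        assert d.overlap == pytest.approx(8 / 12)
        oracle_p = hypergeom_tail(8, 10, 10, 1000)
        assert d.p == pytest.approx(oracle_p, abs=1e-12)
        assert oracle_p < 0.05
        assert d.criterion == "c4"

    def test_exact_half_overlap_is_not_criterion_4(self):
        # |A∩B| = 5, |A∪B| = 10: the 50% threshold is strict.
        a = P("A", *G(7))  # g1..g7
        b = P("B", *G(8, 3))  # g3..g10
        d = merge_decision(a, b, universe_size=500)
        assert d.overlap == 0.5
        assert not d.c4_overlap_gt_50_and_significant
        assert d.p is None  # p computed only when the overlap gate passes

    def test_swap_mode_accepts_single_gene_swap(self):
        a, b = P("A", *G(9), "x"), P("B", *G(9), "y")
        assert not merge_decision(a, b, 100).c2_differ_by_one
        d = merge_decision(a, b, 100, criterion2_mode="swap_or_superset")
        assert d.c2_differ_by_one

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(InvalidUniverseError):
            merge_decision(P("A", *G(10)), P("B", *G(10, 20)), universe_size=15)

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValidationError):
            merge_decision(P("A"), P("B", "g1"), universe_size=10)


class TestCondenseCollection:
    def test_identical_pair_collapses_to_one(self):
        c = PathwayCollection([P("A", "x", "y", "z"), P("B", "x", "y", "z")])
        out, rep = condense_collection(c)
        assert len(out) == 1
        assert out.pathways[0].genes == {"x", "y", "z"}
        assert rep.merge_log[0].criterion == "c1"

    def test_chain_of_one_gene_extensions_merges_fully(self):
        # A, B = A + g6, C = B + g7 over a 100-gene universe. The
        # highest-overlap pair (B, C) merges first by the one-gene rule;
        # A then shares 5 of 7 genes with the union, which the exact test
        # finds significant, completing the collapse.
        c = PathwayCollection(
            [P("A", *G(5)), P("B", *G(6)), P("C", *G(7))], universe=G(100)
        )
        out, rep = condense_collection(c)
        assert len(out) == 1
        assert out.pathways[0].genes == set(G(7))
        assert [e.criterion for e in rep.merge_log] == ["c2", "c4"]

    def test_disjoint_pathways_unchanged(self):
        c = PathwayCollection([P("A", *G(10)), P("B", *G(10, 50))])
        out, rep = condense_collection(c)
        assert len(out) == 2 and rep.merge_log == ()

    def test_idempotent_and_gene_conserving(self, planted_bundle):
        collection, _ = planted_bundle
        once, rep1 = condense_collection(collection)
        twice, rep2 = condense_collection(once)
        assert len(once) <= len(collection)
        assert [p.genes for p in twice] == [p.genes for p in once]
        assert rep2.merge_log == ()
        assert once.gene_union() == collection.gene_union()

    def test_merge_log_replays_to_output(self, planted_bundle):
        collection, _ = planted_bundle
        out, rep = condense_collection(collection)
        assert rep.n_output == rep.n_input - len(rep.merge_log)
        survivors = set(collection.ids)
        for e in rep.merge_log:
            survivors.discard(e.absorbed_id)
            assert e.surviving_id in survivors
        assert survivors == set(out.ids)

    def test_order_insensitive_fixpoint(self):
        cfg = SynthConfig(seed=5, n_base=15, universe_size=300, n_exact_dup=3, n_near_dup=3, n_one_off=3, n_small_subset=3)
        collection, _ = generate_collection(cfg)
        out1, _ = condense_collection(collection)
        shuffled = list(collection.pathways)
        random.Random(42).shuffle(shuffled)
        out2, _ = condense_collection(PathwayCollection(shuffled, universe=collection.universe))
        assert sorted(map(sorted, (p.genes for p in out1.pathways))) == sorted(
            map(sorted, (p.genes for p in out2.pathways))
        )

    def test_provenance_accumulates_absorbed_ids(self):
        c = PathwayCollection(
            [P("A", *G(5)), P("B", *G(6)), P("C", *G(7))], universe=G(100)
        )
        out, _ = condense_collection(c)
        final = out.pathways[0]
        assert set(final.provenance) == {"A", "B", "C"} - {final.id}


class TestExcludeSmall:
    def test_two_gene_pathway_removed_at_default_threshold(self):
        c = PathwayCollection([P("A", "x", "y"), P("B", "x", "y", "z")])
        out, removed = exclude_small(c)
        assert out.ids == ["B"] and removed == ["A"]

    def test_three_gene_pathway_retained_at_boundary(self):
        c = PathwayCollection([P("A", "x", "y", "z")])
        out, removed = exclude_small(c, min_genes=3)
        assert out.ids == ["A"] and removed == []

    def test_empty_collection(self):
        out, removed = exclude_small(PathwayCollection([]))
        assert len(out) == 0 and removed == []

    def test_min_genes_must_be_positive(self):
        with pytest.raises(ValidationError):
            exclude_small(PathwayCollection([]), min_genes=0)
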