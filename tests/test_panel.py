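from __future__ import annotations

import math

import numpy as np
import pytest

from pathcondense.errors import OracleScaleError
from pathcondense.model import AssayAnnotation, AssaySource, Pathway, PathwayCollection
from pathcondense.panel import (
    brute_force_cover,
    coverage_by_source,
    greedy_cover,
    rank_genes,
)

from .conftest import P


def random_instance(rng: np.random.Generator, n_genes=12, n_pathways=8, max_size=4):
    genes = [f"g{i:02d}" for i in range(n_genes)]
    pathways = []
    for j in range(n_pathways):
        size = int(rng.integers(1, max_size + 1))
        member = rng.choice(genes, size=size, replace=False)
        pathways.append(P(f"P{j}", *map(str, member)))
    return PathwayCollection(pathways)


class TestRankGenes:
    def test_more_pathways_ranks_higher(self):
        c = PathwayCollection(
            [P("P1", "a", "b"), P("P2", "a", "c"), P("P3", "a"), P("P4", "b")]
        )
        order = [r.gene for r in rank_genes(c)]
        assert order.index("a") < order.index("b") < order.index("c")

    def test_smaller_mean_pathway_size_breaks_ties(self):
        # x and y both in 2 pathways; x's pathways are smaller
        c = PathwayCollection(
            [
                P("S1", "x", "a"),
                P("S2", "x", "b"),
                P("L1", "y", *[f"f{i}" for i in range(9)]),
                P("L2", "y", *[f"h{i}" for i in range(9)]),
            ]
        )
        ranks = {r.gene: r for r in rank_genes(c)}
        assert ranks["x"].mean_pathway_size < ranks["y"].mean_pathway_size
        order = [r.gene for r in rank_genes(c)]
        assert order.index("x") < order.index("y")

    def test_assayed_gene_outranks_busier_unassayed_gene(self):
        c = PathwayCollection(
            [P("P1", "u", "a"), P("P2", "u", "b"), P("P3", "u"), P("P4", "u", "v"), P("P5", "v")]
        )
        anns = [AssayAnnotation(gene="v", sources=frozenset({AssaySource.TOX21}))]
        order = [r.gene for r in rank_genes(c, anns)]
        assert order[0] == "v"  # assayed, though u sits in 4 pathways vs 2


class TestGreedyCover:
    def test_universal_gene_gives_singleton_panel(self):
        c = PathwayCollection([P(f"P{i}", "hub", f"g{i}") for i in range(5)])
        res = greedy_cover(c)
        assert res.selected == ("hub",)
        assert set(res.covered) == {f"P{i}" for i in range(5)}

    def test_three_pathway_chain_needs_two_genes(self):
        c = PathwayCollection([P("P1", "g1", "g2"), P("P2", "g2", "g3"), P("P3", "g3", "g4")])
        res = greedy_cover(c)
        assert res.n_selected == 2
        assert brute_force_cover(c).n_selected == 2

    def test_cover_is_always_valid(self, planted_bundle):
        collection, _ = planted_bundle
        res = greedy_cover(collection)
        chosen = set(res.selected)
        for p in collection:
            assert p.genes & chosen, f"pathway {p.id} uncovered"
            assert res.covered[p.id] in p.genes

    def test_every_selected_gene_covered_something_new(self, planted_bundle):
        collection, _ = planted_bundle
        res = greedy_cover(collection)
        first_cover = set(res.covered.values())
        assert first_cover == set(res.selected)

    def test_deterministic_under_pathway_permutation(self, planted_bundle):
        collection, _ = planted_bundle
        rev = PathwayCollection(list(reversed(collection.pathways)), universe=collection.universe)
        assert greedy_cover(collection).selected == greedy_cover(rev).selected

    def test_full_assay_annotation_reproduces_unprioritized_panel(self, planted_bundle):
        """When every gene has an assay the priority tier is constant, so
        both variants select the identical panel."""
        collection, _ = planted_bundle
        anns = [
            AssayAnnotation(gene=g, sources=frozenset({AssaySource.PUBCHEM}))
            for g in collection.gene_union()
        ]
        assert greedy_cover(collection, anns).selected == greedy_cover(collection).selected

    def test_adaptive_mode_is_valid_and_no_larger_than_static_here(self, planted_bundle):
        collection, _ = planted_bundle
        res = greedy_cover(collection, adaptive=True)
        chosen = set(res.selected)
        assert all(p.genes & chosen for p in collection)

    def test_empty_gene_pathway_reported_not_fatal(self):
        pw = Pathway(id="E", name="empty", genes=frozenset())
        c = PathwayCollection([pw, P("P1", "a")])
        res = greedy_cover(c)
        assert res.uncoverable == ("E",)
        assert res.selected == ("a",)


class TestBruteForceOracle:
    def test_trivial_instances(self):
        assert brute_force_cover(PathwayCollection([P("P1", "g1", "g2")])).n_selected == 1
        two = PathwayCollection([P("P1", "a", "b"), P("P2", "c", "d")])
        assert brute_force_cover(two).n_selected == 2

    def test_refuses_large_universe(self):
        c = PathwayCollection([P("P1", *[f"g{i}" for i in range(21)])])
        with pytest.raises(OracleScaleError):
            brute_force_cover(c)

    def test_agrees_with_integer_program(self):
        """Cross-check the enumeration oracle against an independent
        integer-program formulation of minimum set cover."""
        from scipy.optimize import LinearConstraint, milp

        rng = np.random.default_rng(123)
        for _ in range(10):
            c = random_instance(rng)
            genes = sorted(c.gene_union())
            pos = {g: i for i, g in enumerate(genes)}
            A = np.zeros((len(c), len(genes)))
            for r, p in enumerate(c):
                for g in p.genes:
                    A[r, pos[g]] = 1
            res = milp(
                c=np.ones(len(genes)),
                constraints=LinearConstraint(A, lb=1),
                integrality=np.ones(len(genes)),
                bounds=(0, 1),
            )
            assert res.success
            assert brute_force_cover(c).n_selected == round(res.fun)

    def test_greedy_between_minimum_and_harmonic_bound(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            c = random_instance(rng)
            greedy = greedy_cover(c)
            exact = brute_force_cover(c)
            assert set(greedy.covered) == {p.id for p in c if p.genes}
            max_freq = max(
                sum(1 for p in c if g in p.genes) for g in c.gene_union()
            )
            bound = exact.n_selected * (1 + math.log(max_freq))
            assert exact.n_selected <= greedy.n_selected <= bound


class TestCoverageBySource:
    def test_highest_priority_source_wins(self):
        c = PathwayCollection([P("P1", "a", "b"), P("P2", "c")])
        anns = [
            AssayAnnotation(gene="a", sources=frozenset({AssaySource.PUBCHEM})),
            AssayAnnotation(gene="b", sources=frozenset({AssaySource.TOX21, AssaySource.COMMERCIAL})),
        ]
        cov = coverage_by_source(c, anns)
        assert cov.pathway_source["P1"] == "TOX21"  # Tox21 beats PubChem
        assert cov.pathway_source["P2"] is None
        assert cov.n_uncovered == 1
        assert cov.fraction("TOX21") == 0.5
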