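from __future__ import annotations

import random

import pytest

from pathcondense.errors import ValidationError
from pathcondense.model import PathwayCollection
from pathcondense.synth import SynthConfig, generate_collection
from pathcondense.tagging import (
    ALL_TAGS,
    DEFAULT_VOCABULARY,
    assign_tags,
    tag_by_gene_annotations,
    tag_by_keywords,
)

from .conftest import P


def pathway_with_tagged_genes(n_genes: int, n_tagged: int, tag: str = "Cell death"):
    genes = [f"g{i}" for i in range(n_genes)]
    collection = PathwayCollection([P("X", *genes)])
    gene_tags = {g: frozenset({tag}) for g in genes[:n_tagged]}
    return collection, gene_tags


class TestGeneBasedThresholds:
    @pytest.mark.parametrize(
        "n_genes, n_tagged, assigned",
        [
            (40, 4, True),  # 4 genes and exactly 10%: both thresholds met
            (50, 4, False),  # 4 genes but only 8%
            (9, 3, False),  # 33% but only 3 genes
        ],
    )
    def test_both_thresholds_must_hold(self, n_genes, n_tagged, assigned):
        collection, gene_tags = pathway_with_tagged_genes(n_genes, n_tagged)
        out = tag_by_gene_annotations(collection, gene_tags)
        assert bool(out) is assigned
        if assigned:
            (a,) = out
            assert a.n_tagged_genes == n_tagged
            assert a.frac_tagged == pytest.approx(n_tagged / n_genes)

    def test_every_assignment_satisfies_printed_thresholds(self, planted_bundle):
        collection, ledger = planted_bundle
        cfg = SynthConfig(seed=3, tag_structure={"Cell death": 0.12, "DNA repair": 0.15})
        c, led = generate_collection(cfg)
        for a in tag_by_gene_annotations(c, led.gene_tags):
            assert a.n_tagged_genes >= 4
            assert a.frac_tagged >= 0.10

    def test_unknown_tag_rejected(self):
        collection, _ = pathway_with_tagged_genes(40, 4)
        with pytest.raises(ValidationError):
            tag_by_gene_annotations(collection, {"g0": frozenset({"Not a real tag"})})

    def test_multi_tag_genes_count_for_every_tag(self):
        genes = [f"g{i}" for i in range(10)]
        c = PathwayCollection([P("X", *genes)])
        gene_tags = {g: frozenset({"Cell death", "Cancer"}) for g in genes[:4]}
        tags = {a.tag for a in tag_by_gene_annotations(c, gene_tags)}
        assert tags == {"Cell death", "Cancer"}


class TestKeywordTagging:
    def test_keyword_in_title_assigns_tag(self):
        c = PathwayCollection([P("X", "g1", name="Purine catabolism")])
        lex = {"Purine": frozenset({"Nucleic acid metabolism"})}
        [a] = tag_by_keywords(c, lex)
        assert a.tag == "Nucleic acid metabolism"
        assert a.matched_keyword == "Purine"

    def test_hyphenated_title_matches_all_keywords(self):
        c = PathwayCollection([P("X", "g1", name="HIV-induced T cell apoptosis")])
        lex = {
            "HIV": frozenset({"Infectious disease"}),
            "T cell": frozenset({"Immune system"}),
            "apoptosis": frozenset({"Cell death"}),
        }
        tags = {a.tag for a in tag_by_keywords(c, lex)}
        assert tags == {"Infectious disease", "Immune system", "Cell death"}

    def test_no_keyword_no_assignment(self):
        c = PathwayCollection([P("X", "g1", name="Glucose sensing")])
        assert tag_by_keywords(c, {"Purine": frozenset({"Nucleic acid metabolism"})}) == []

    def test_match_is_whole_word_and_case_insensitive(self):
        lex = {"HIV": frozenset({"Infectious disease"})}
        hit = PathwayCollection([P("X", "g1", name="hiv life cycle")])
        miss = PathwayCollection([P("Y", "g1", name="SHIVER response")])
        assert len(tag_by_keywords(hit, lex)) == 1
        assert tag_by_keywords(miss, lex) == []


class TestAssignTags:
    def test_union_keeps_both_provenance_records(self):
        genes = [f"g{i}" for i in range(40)]
        c = PathwayCollection([P("X", *genes, name="Apoptosis signaling")])
        gene_tags = {g: frozenset({"Cell death"}) for g in genes[:4]}
        lex = {"apoptosis": frozenset({"Cell death"})}
        report = assign_tags(c, gene_tags, lex)
        assert report.by_pathway["X"] == {"Cell death"}
        assert {a.method for a in report.assignments} == {"gene_based", "keyword"}

    def test_planted_tag_structure_recovered_exactly(self):
        cfg = SynthConfig(seed=11, tag_structure={"Cell death": 0.12, "Transcription": 0.2})
        c, led = generate_collection(cfg)
        report = assign_tags(c, led.gene_tags, lexicon={})
        recovered = {pid: tags for pid, tags in report.by_pathway.items() if tags}
        assert recovered == dict(led.planted_tags)

    def test_empty_inputs_give_zero_assignments(self):
        c = PathwayCollection([P("X", "g1", name="Anything")])
        report = assign_tags(c, {}, lexicon={})
        assert report.assignments == ()
        assert report.frac_tagged == 0.0

    def test_determinism_under_pathway_order(self):
        cfg = SynthConfig(seed=2, n_base=20, n_exact_dup=0, n_near_dup=0, n_one_off=0, n_small_subset=0, tag_structure={"Cancer": 0.15}, n_pathways_per_tag=3)
        c, led = generate_collection(cfg)
        shuffled = list(c.pathways)
        random.Random(1).shuffle(shuffled)
        c2 = PathwayCollection(shuffled, universe=c.universe)
        r1 = assign_tags(c, led.gene_tags, lexicon={})
        r2 = assign_tags(c2, led.gene_tags, lexicon={})
        assert r1.assignments == r2.assignments

    def test_lexicon_growth_is_monotone(self):
        c = PathwayCollection([P("X", "g1", name="Purine catabolism in T cell")])
        small = {"Purine": frozenset({"Nucleic acid metabolism"})}
        big = dict(small, **{"T cell": frozenset({"Immune system"})})
        tags_small = {a.tag for a in tag_by_keywords(c, small)}
        tags_big = {a.tag for a in tag_by_keywords(c, big)}
        assert tags_small <= tags_big


def test_default_vocabulary_has_51_unique_tags_in_7_categories():
    assert len(DEFAULT_VOCABULARY) == 7
    assert len(ALL_TAGS) == 51
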