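"""Automated pathway tagging.

Two complementary rules assign functional-category tags to pathways:

* **gene-based** — a tag is assigned when enough of the pathway's genes
  carry it in a gene -> tag annotation table (derived upstream from
  GO-slim-style annotations): at least 10% of the pathway's genes AND at
  least 4 genes must share the tag;
* **keyword** — a tag is assigned when a keyword from a lexicon occurs
  in the pathway title (case-insensitive, on word boundaries, with
  hyphen and slash treated as boundaries so "HIV-induced" matches "HIV").

The shipped vocabulary contains 51 tags in seven categories; the
gene -> tag mapping itself is an input (the ontology-to-tag step is a
curation product, not recomputed here).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ValidationError
from .model import PathwayCollection

#: Default tag vocabulary: 51 tags grouped into seven categories.
DEFAULT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "Major Systems": (
        "Circulatory system",
        "Digestive system",
        "Endocrine system",
        "Excretory system",
        "Immune system",
        "Musculoskeletal system",
        "Nervous system",
        "Sensory system",
    ),
    "Cell Cycle": (
        "Cell cycle",
        "Cell growth",
        "Cell death",
        "Cell division",
        "Cell proliferation",
        "Reproduction",
    ),
    "Genetic Information Processing": (
        "DNA replication",
        "DNA repair",
        "Transcription",
        "RNA processing",
        "Translation",
        "Protein folding, sorting, and degradation",
        "Protein modification",
    ),
    "Metabolism": (
        "Nucleic acid metabolism",
        "Carbohydrate metabolism",
        "Protein metabolism",
        "Lipid metabolism",
        "Vitamin and cofactor metabolism",
        "Small molecule metabolism",
        "Xenobiotic metabolism",
        "Energy metabolism",
    ),
    "Development": (
        "Development",
        "Adhesion",
        "Cell differentiation",
        "Cell motility",
    ),
    "Signaling": (
        "Cell signaling",
        "G-protein coupled receptor",
        "Nuclear receptor",
        "Transcriptional regulation",
        "Stress response",
        "Environmental adaptation",
        "Chronology",
        "Transport",
    ),
    "Disease": (
        "Cancer",
        "Cardiovascular disease",
        "Genetic disease",
        "Immune disease",
        "Infectious disease",
        "Neurological disease",
        "Physical disorder",
        "Endocrine and metabolic disease",
        "Sepsis",
        "Substance dependence",
    ),
}

ALL_TAGS: frozenset[str] = frozenset(t for tags in DEFAULT_VOCABULARY.values() for t in tags)
assert len(ALL_TAGS) == 51

#: A starter keyword -> tag lexicon for title-based tagging. Real analyses
#: will extend this; the entries here cover the canonical examples
#: (nucleobase chemistry -> nucleic acid metabolism; "HIV-induced T cell
#: apoptosis" -> infectious disease / immune system / cell death). Note
#: the immune tag: the vocabulary has "Immune system", so "T cell" maps
#: there rather than to a free-standing "Immune response" tag.
DEFAULT_LEXICON: dict[str, frozenset[str]] = {
    kw: frozenset(tags)
    for kw, tags in {
        "Nucleobase": ["Nucleic acid metabolism"],
        "Nucleotide": ["Nucleic acid metabolism"],
        "Nucleoside": ["Nucleic acid metabolism"],
        "Purine": ["Nucleic acid metabolism"],
        "Pyrimidine": ["Nucleic acid metabolism"],
        "HIV": ["Infectious disease"],
        "T cell": ["Immune system"],
        "B cell": ["Immune system"],
        "apoptosis": ["Cell death"],
        "cell death": ["Cell death"],
        "cell cycle": ["Cell cycle"],
        "DNA repair": ["DNA repair"],
        "DNA replication": ["DNA replication"],
        "transcription": ["Transcription"],
        "translation": ["Translation"],
        "cancer": ["Cancer"],
        "carcinoma": ["Cancer"],
        "GPCR": ["G-protein coupled receptor"],
        "glycolysis": ["Carbohydrate metabolism", "Energy metabolism"],
        "lipid": ["Lipid metabolism"],
        "xenobiotic": ["Xenobiotic metabolism"],
        "neuronal": ["Nervous system"],
        "transport": ["Transport"],
        "adhesion": ["Adhesion"],
        "differentiation": ["Cell differentiation"],
        "proliferation": ["Cell proliferation"],
    }.items()
}


@dataclass(frozen=True)
class TagAssignment:
    """One (pathway, tag) assignment with its supporting evidence."""

    pathway_id: str
    tag: str
    method: str  # "gene_based" | "keyword"
    n_tagged_genes: int | None = None
    frac_tagged: float | None = None
    matched_keyword: str | None = None


def _check_vocabulary(tags: Iterable[str], vocabulary: frozenset[str] | None) -> None:
    if vocabulary is None:
        return
    unknown = sorted(set(tags) - vocabulary)
    if unknown:
        raise ValidationError(f"tag(s) outside vocabulary: {unknown[:5]}")


def tag_by_gene_annotations(
    collection: PathwayCollection,
    gene_tags: Mapping[str, frozenset[str] | set[str]],
    *,
    min_frac: float = 0.10,
    min_genes: int = 4,
    vocabulary: frozenset[str] | None = ALL_TAGS,
) -> list[TagAssignment]:
    """Assign a tag to a pathway when >= ``min_frac`` of its genes and at
    least ``min_genes`` genes carry that tag.

    A gene with several tags contributes to every one of them. Output is
    sorted by (pathway id, tag) and independent of pathway order.
    """
    for tags in gene_tags.values():
        _check_vocabulary(tags, vocabulary)
    out: list[TagAssignment] = []
    for p in collection:
        counts: dict[str, int] = {}
        for g in p.genes:
            for t in gene_tags.get(g, ()):
                counts[t] = counts.get(t, 0) + 1
        for t in sorted(counts):
            n = counts[t]
            frac = n / p.n_genes
            if n >= min_genes and frac >= min_frac:
                out.append(
                    TagAssignment(
                        pathway_id=p.id, tag=t, method="gene_based", n_tagged_genes=n, frac_tagged=frac
                    )
                )
    return sorted(out, key=lambda a: (a.pathway_id, a.tag))


def _keyword_pattern(keyword: str) -> re.Pattern[str]:
    # Word boundaries that also break at hyphens and slashes; alphanumeric
    # context on either side blocks the match ("HIV-induced" matches "HIV",
    # "SHIVER" does not).
    return re.compile(rf"(?<![A-Za-z0-9]){re.escape(keyword)}(?![A-Za-z0-9])", re.IGNORECASE)


def tag_by_keywords(
    collection: PathwayCollection,
    lexicon: Mapping[str, frozenset[str] | set[str]] = DEFAULT_LEXICON,
    *,
    vocabulary: frozenset[str] | None = ALL_TAGS,
) -> list[TagAssignment]:
    """Assign tags whose lexicon keywords occur in the pathway title."""
    for tags in lexicon.values():
        _check_vocabulary(tags, vocabulary)
    patterns = {kw: _keyword_pattern(kw) for kw in lexicon}
    out: list[TagAssignment] = []
    for p in collection:
        hits: dict[str, str] = {}
        for kw in sorted(lexicon):
            if patterns[kw].search(p.name):
                for t in sorted(lexicon[kw]):
                    hits.setdefault(t, kw)
        for t in sorted(hits):
            out.append(TagAssignment(pathway_id=p.id, tag=t, method="keyword", matched_keyword=hits[t]))
    return sorted(out, key=lambda a: (a.pathway_id, a.tag))


@dataclass(frozen=True)
class TagReport:
    """Union of gene-based and keyword tagging over a collection."""

    assignments: tuple[TagAssignment, ...]
    by_pathway: dict[str, frozenset[str]]
    frac_tagged: float  # fraction of pathways with at least one tag


def assign_tags(
    collection: PathwayCollection,
    gene_tags: Mapping[str, frozenset[str] | set[str]],
    lexicon: Mapping[str, frozenset[str] | set[str]] = DEFAULT_LEXICON,
    *,
    min_frac: float = 0.10,
    min_genes: int = 4,
    vocabulary: frozenset[str] | None = ALL_TAGS,
) -> TagReport:
    """Combine both tagging methods; per-pathway tag sets are their union.

    Every individual assignment (with its method and evidence) is kept,
    so a tag found by both methods carries two provenance records.
    """
    gene_based = tag_by_gene_annotations(
        collection, gene_tags, min_frac=min_frac, min_genes=min_genes, vocabulary=vocabulary
    )
    keyword = tag_by_keywords(collection, lexicon, vocabulary=vocabulary)
    assignments = tuple(sorted(gene_based + keyword, key=lambda a: (a.pathway_id, a.tag, a.method)))
    by_pathway: dict[str, set[str]] = {p.id: set() for p in collection}
    for a in assignments:
        by_pathway[a.pathway_id].add(a.tag)
    n = len(collection)
    frac = (sum(1 for tags in by_pathway.values() if tags) / n) if n else 0.0
    return TagReport(
        assignments=assignments,
        by_pathway={k: frozenset(v) for k, v in by_pathway.items()},
        frac_tagged=frac,
    )
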