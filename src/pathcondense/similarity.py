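"""Pairwise gene-component similarity and collection-level redundancy statistics.

The similarity score between two pathways is the number of shared genes
divided by the total number of unique genes in the two — the Jaccard
index of the gene sets. A score of 1 means identical gene components;
``1 - s`` is a metric (the Jaccard distance).
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import InsufficientInputError, UndefinedSimilarityError
from .model import Pathway, PathwayCollection

#: Gene-count bins used for the pathway size histogram.
SIZE_BINS = ("1", "2", "3", "4", "5", "6-10", "11-20", "21-50", "51-100", ">100")


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Jaccard index |A∩B| / |A∪B| of two sets; undefined when both are empty."""
    if not a and not b:
        raise UndefinedSimilarityError("similarity of two empty sets is undefined")
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return inter / union


def similarity(a: Pathway, b: Pathway) -> float:
    """Similarity score of two pathways: shared genes over total unique genes."""
    return jaccard(a.genes, b.genes)


def _size_bin(n: int) -> str:
    if n <= 5:
        return str(n)
    if n <= 10:
        return "6-10"
    if n <= 20:
        return "11-20"
    if n <= 50:
        return "21-50"
    if n <= 100:
        return "51-100"
    return ">100"


@dataclass(frozen=True)
class BestMatch:
    """Best-scoring partner of a pathway within a collection (self excluded)."""

    pathway_id: str
    partner_id: str
    score: float


@dataclass(frozen=True)
class RedundancyStats:
    """Collection-level redundancy and size summary.

    frac_exact_duplicate
        Fraction of pathways whose best match has identical gene
        components (score exactly 1).
    frac_close_match
        Fraction whose best match shares over 90% of genes (score > 0.9;
        includes the exact duplicates).
    size_histogram
        Pathway counts per gene-count bin (:data:`SIZE_BINS`).
    frac_le5, frac_single_gene
        Fractions of pathways with <=5 genes and exactly 1 gene.
    best_matches
        The per-pathway best-match table underlying the fractions.
    """

    frac_exact_duplicate: float
    frac_close_match: float
    size_histogram: dict[str, int]
    frac_le5: float
    frac_single_gene: float
    best_matches: tuple[BestMatch, ...]


def best_matches(
    collection: PathwayCollection, exclude_same_source: bool = False
) -> list[BestMatch]:
    """For each pathway, the highest-similarity partner in the collection.

    ``exclude_same_source`` restricts candidate partners to pathways from
    a different source database. Ties are broken by partner id.
    """
    if len(collection) < 2:
        raise InsufficientInputError("best-match statistics need at least 2 pathways")
    out: list[BestMatch] = []
    paths = collection.pathways
    for p in paths:
        best_s, best_id = -1.0, ""
        for q in paths:
            if q.id == p.id:
                continue
            if exclude_same_source and q.source == p.source:
                continue
            s = similarity(p, q)
            if s > best_s or (s == best_s and q.id < best_id):
                best_s, best_id = s, q.id
        if best_id:
            out.append(BestMatch(pathway_id=p.id, partner_id=best_id, score=best_s))
    return out


def redundancy_stats(
    collection: PathwayCollection, exclude_same_source: bool = False
) -> RedundancyStats:
    """Redundancy and size statistics over a collection (>=2 pathways)."""
    matches = best_matches(collection, exclude_same_source=exclude_same_source)
    n = len(collection)
    n_exact = sum(1 for m in matches if m.score == 1.0)
    n_close = sum(1 for m in matches if m.score > 0.9)
    hist = {b: 0 for b in SIZE_BINS}
    for p in collection:
        hist[_size_bin(p.n_genes)] += 1
    return RedundancyStats(
        frac_exact_duplicate=n_exact / n,
        frac_close_match=n_close / n,
        size_histogram=hist,
        frac_le5=sum(1 for p in collection if p.n_genes <= 5) / n,
        frac_single_gene=sum(1 for p in collection if p.n_genes == 1) / n,
        best_matches=tuple(matches),
    )
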