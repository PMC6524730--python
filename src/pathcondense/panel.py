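"""Minimal assay-panel design by greedy set cover.

To probe every pathway with as few gene-target assays as possible,
genes are ranked so that genes appearing in more pathways — and, among
those, in smaller pathways — come first; an optional assay-availability
tier puts assayable genes ahead of the rest. A single scan of the
ranked list then collects each gene that covers at least one
still-uncovered pathway, stopping when every non-empty pathway is
covered. An adaptive variant re-scores genes on residual coverage at
each step. For oracle-scale instances an exhaustive enumeration returns
a provably minimum cover.

Also here: the source-priority coverage accounting — for each pathway,
which assay source tier (Tox21 > NCATS > PubChem > commercial) covers
it, counting only the highest-priority source.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InsufficientInputError, OracleScaleError
from .model import AssayAnnotation, AssaySource, PathwayCollection


@dataclass(frozen=True)
class GeneRank:
    """Ranking record for one gene."""

    gene: str
    n_pathways: int
    mean_pathway_size: float
    has_assay: bool


def _gene_index(collection: PathwayCollection) -> dict[str, list[str]]:
    """gene -> ids of pathways containing it."""
    idx: dict[str, list[str]] = {}
    for p in collection:
        for g in p.genes:
            idx.setdefault(g, []).append(p.id)
    return idx


def rank_genes(
    collection: PathwayCollection, assays: Sequence[AssayAnnotation] | None = None
) -> list[GeneRank]:
    """Rank genes for panel selection.

    Sort key: assay availability first (only when ``assays`` is given),
    then participation in more pathways, then smaller mean size of the
    pathways the gene participates in, then gene id — a deterministic
    total order.
    """
    if not len(collection):
        raise InsufficientInputError("cannot rank genes of an empty collection")
    sizes = {p.id: p.n_genes for p in collection}
    assayed = {a.gene for a in assays} if assays is not None else None
    ranks = []
    for g, pids in _gene_index(collection).items():
        ranks.append(
            GeneRank(
                gene=g,
                n_pathways=len(pids),
                mean_pathway_size=sum(sizes[i] for i in pids) / len(pids),
                has_assay=(g in assayed) if assayed is not None else False,
            )
        )
    ranks.sort(key=lambda r: (not r.has_assay, -r.n_pathways, r.mean_pathway_size, r.gene))
    return ranks


@dataclass(frozen=True)
class CoverResult:
    """A gene panel covering the collection.

    ``covered`` maps each covered pathway to the selected gene that
    first covered it; ``uncoverable`` lists pathways with no genes.
    """

    selected: tuple[str, ...]
    covered: dict[str, str]
    uncoverable: tuple[str, ...]

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def greedy_cover(
    collection: PathwayCollection,
    assays: Sequence[AssayAnnotation] | None = None,
    *,
    adaptive: bool = False,
) -> CoverResult:
    """Select a gene panel covering every non-empty pathway.

    Static mode (default) scans the :func:`rank_genes` list once,
    collecting each gene that covers at least one new pathway. Adaptive
    mode repeatedly picks the gene covering the most uncovered pathways
    (ties broken by the static rank order). Both stop when every
    coverable pathway is covered, and both are deterministic under any
    permutation of the input pathways.
    """
    if not len(collection):
        raise InsufficientInputError("cannot cover an empty collection")
    uncoverable = tuple(sorted(p.id for p in collection if not p.genes))
    uncovered = {p.id for p in collection if p.genes}
    membership = _gene_index(collection)
    ranked = [r.gene for r in rank_genes(collection, assays)]
    selected: list[str] = []
    covered: dict[str, str] = {}

    if not adaptive:
        for g in ranked:
            if not uncovered:
                break
            new = [pid for pid in membership[g] if pid in uncovered]
            if new:
                selected.append(g)
                for pid in new:
                    covered[pid] = g
                uncovered.difference_update(new)
    else:
        rank_pos = {g: i for i, g in enumerate(ranked)}
        while uncovered:
            best = min(
                membership,
                key=lambda g: (-sum(pid in uncovered for pid in membership[g]), rank_pos[g]),
            )
            new = [pid for pid in membership[best] if pid in uncovered]
            if not new:  # pragma: no cover - uncovered implies some gene covers
                break
            selected.append(best)
            for pid in new:
                covered[pid] = best
            uncovered.difference_update(new)

    return CoverResult(selected=tuple(selected), covered=covered, uncoverable=uncoverable)


#: Enumeration bound for the exhaustive oracle.
BRUTE_FORCE_MAX_GENES = 20


def brute_force_cover(collection: PathwayCollection) -> CoverResult:
    """Provably minimum-cardinality cover by exhaustive enumeration.

    Only for instances whose pathways span at most
    :data:`BRUTE_FORCE_MAX_GENES` genes. Among minimum covers the
    lexicographically smallest gene tuple is returned.
    """
    membership = _gene_index(collection)
    genes = sorted(membership)
    if len(genes) > BRUTE_FORCE_MAX_GENES:
        raise OracleScaleError(
            f"exhaustive cover limited to {BRUTE_FORCE_MAX_GENES} genes, got {len(genes)}"
        )
    uncoverable = tuple(sorted(p.id for p in collection if not p.genes))
    targets = {p.id: p.genes for p in collection if p.genes}
    if not targets:
        return CoverResult(selected=(), covered={}, uncoverable=uncoverable)
    for size in range(1, len(genes) + 1):
        for combo in itertools.combinations(genes, size):
            chosen = set(combo)
            if all(gs & chosen for gs in targets.values()):
                covered = {
                    pid: next(g for g in combo if g in gs) for pid, gs in targets.items()
                }
                return CoverResult(selected=combo, covered=covered, uncoverable=uncoverable)
    raise AssertionError("unreachable: every non-empty pathway is covered by all genes")


@dataclass(frozen=True)
class SourceCoverage:
    """Pathway coverage by assay source, counting only the top-priority source."""

    by_source: dict[str, int]  # source name -> number of pathways
    n_uncovered: int
    n_pathways: int
    pathway_source: dict[str, str | None]  # pathway id -> best source name or None

    def fraction(self, source: str) -> float:
        return self.by_source.get(source, 0) / self.n_pathways if self.n_pathways else 0.0


def coverage_by_source(
    collection: PathwayCollection, assays: Iterable[AssayAnnotation]
) -> SourceCoverage:
    """Attribute each pathway to the highest-priority source with an assay
    for any of its genes; pathways with no assayable gene count as uncovered.
    """
    gene_best: dict[str, AssaySource] = {}
    for a in assays:
        best = a.best_source
        cur = gene_best.get(a.gene)
        if cur is None or best.priority < cur.priority:
            gene_best[a.gene] = best
    pathway_source: dict[str, str | None] = {}
    by_source: dict[str, int] = {s.name: 0 for s in AssaySource}
    n_uncovered = 0
    for p in collection:
        sources = [gene_best[g] for g in p.genes if g in gene_best]
        if sources:
            best = min(sources, key=lambda s: s.priority)
            pathway_source[p.id] = best.name
            by_source[best.name] += 1
        else:
            pathway_source[p.id] = None
            n_uncovered += 1
    return SourceCoverage(
        by_source=by_source,
        n_uncovered=n_uncovered,
        n_pathways=len(collection),
        pathway_source=pathway_source,
    )
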