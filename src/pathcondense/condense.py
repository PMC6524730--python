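"""Iterative condensation of redundant pathways.

Two pathways are mergeable when any of four criteria holds:

1. their gene-component overlap (shared genes over total unique genes)
   exceeds 90%;
2. they differ by only one gene (symmetric difference of size 1);
3. one pathway has fewer than 3 genes, all contained in the other;
4. their overlap exceeds 50% and the shared-gene count is significant at
   p < 0.05 by a one-sided Fisher's exact test against the collection's
   gene universe.

Merging replaces the pair by the union of their gene sets and is
repeated until no pair meets any criterion (a fixpoint). The pair with
the highest overlap is merged first at every step, which makes the
procedure deterministic and insensitive to input order; the merged
pathway keeps the identity of the larger member (ties: lexicographically
smaller id) and records the absorbed ids as provenance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from ._stats import overlap_pvalue
from .errors import InvalidUniverseError, ValidationError
from .model import Pathway, PathwayCollection
from .similarity import jaccard

CRITERION_NAMES = ("c1", "c2", "c3", "c4")


@dataclass(frozen=True)
class MergeDecision:
    """Outcome of evaluating the four merge criteria on one pathway pair.

    ``p`` is computed only when needed for criterion 4 (overlap above the
    low threshold and criteria 1-3 all false) and is ``None`` otherwise.
    ``criterion`` is the first satisfied criterion in order c1..c4, or
    ``None`` when the pair is not mergeable.
    """

    pair: tuple[str, str]
    c1_overlap_gt_90: bool
    c2_differ_by_one: bool
    c3_small_subset: bool
    c4_overlap_gt_50_and_significant: bool
    overlap: float
    p: float | None

    @property
    def mergeable(self) -> bool:
        return (
            self.c1_overlap_gt_90
            or self.c2_differ_by_one
            or self.c3_small_subset
            or self.c4_overlap_gt_50_and_significant
        )

    @property
    def criterion(self) -> str | None:
        flags = (
            self.c1_overlap_gt_90,
            self.c2_differ_by_one,
            self.c3_small_subset,
            self.c4_overlap_gt_50_and_significant,
        )
        for name, flag in zip(CRITERION_NAMES, flags):
            if flag:
                return name
        return None


def merge_decision(
    a: Pathway,
    b: Pathway,
    universe_size: int,
    *,
    overlap_high: float = 0.9,
    overlap_low: float = 0.5,
    alpha: float = 0.05,
    criterion2_mode: str = "symmetric_difference",
) -> MergeDecision:
    """Evaluate the four merge criteria for a pathway pair.

    ``criterion2_mode`` selects the reading of "differ by only one gene":
    ``"symmetric_difference"`` (default) requires |A Δ B| = 1, i.e. one
    set is the other plus exactly one gene; ``"swap_or_superset"``
    additionally accepts equal-size sets differing by a single gene on
    each side (one gene swapped, |A Δ B| = 2 with |A| = |B|).
    """
    if not a.genes or not b.genes:
        raise ValidationError("merge criteria need non-empty gene sets")
    union = a.genes | b.genes
    if universe_size < len(union):
        raise InvalidUniverseError(
            f"universe size {universe_size} smaller than |A∪B| = {len(union)}"
        )
    inter = a.genes & b.genes
    s = len(inter) / len(union)

    c1 = s > overlap_high
    sym_diff = len(union) - len(inter)
    if criterion2_mode == "symmetric_difference":
        c2 = sym_diff == 1
    elif criterion2_mode == "swap_or_superset":
        c2 = sym_diff == 1 or (len(a.genes) == len(b.genes) and sym_diff == 2)
    else:
        raise ValueError(f"unknown criterion2_mode {criterion2_mode!r}")
    small, large = (a, b) if a.n_genes <= b.n_genes else (b, a)
    c3 = small.n_genes < 3 and small.genes <= large.genes

    p: float | None = None
    c4 = False
    if s > overlap_low:
        p = overlap_pvalue(len(inter), a.n_genes, b.n_genes, universe_size)
        c4 = p < alpha

    return MergeDecision(
        pair=(a.id, b.id),
        c1_overlap_gt_90=c1,
        c2_differ_by_one=c2,
        c3_small_subset=c3,
        c4_overlap_gt_50_and_significant=c4,
        overlap=s,
        p=p,
    )


@dataclass(frozen=True)
class MergeEvent:
    surviving_id: str
    absorbed_id: str
    criterion: str
    overlap: float


@dataclass(frozen=True)
class CondensationReport:
    """Audit trail of one condensation run."""

    n_input: int
    n_output: int
    merge_log: tuple[MergeEvent, ...]
    n_iterations: int

    def __post_init__(self) -> None:
        assert self.n_output == self.n_input - len(self.merge_log)


def _survivor_absorbed(a: Pathway, b: Pathway) -> tuple[Pathway, Pathway]:
    """Larger pathway survives; ties go to the lexicographically smaller id."""
    if a.n_genes != b.n_genes:
        return (a, b) if a.n_genes > b.n_genes else (b, a)
    return (a, b) if a.id < b.id else (b, a)


def condense_collection(
    collection: PathwayCollection,
    *,
    overlap_high: float = 0.9,
    overlap_low: float = 0.5,
    alpha: float = 0.05,
    criterion2_mode: str = "symmetric_difference",
) -> tuple[PathwayCollection, CondensationReport]:
    """Merge redundant pathways to fixpoint.

    Returns the condensed collection (original pathway order preserved
    for survivors; absorbed ids accumulated as provenance) and a report
    whose merge log replays to the output. The Fisher background N is
    the collection universe size, held fixed throughout.
    """
    universe_size = len(collection.universe)
    alive: dict[str, Pathway] = {p.id: p for p in collection.pathways}
    order = {p.id: i for i, p in enumerate(collection.pathways)}
    kwargs = dict(
        overlap_high=overlap_high,
        overlap_low=overlap_low,
        alpha=alpha,
        criterion2_mode=criterion2_mode,
    )

    def decide(x: str, y: str) -> MergeDecision:
        return merge_decision(alive[x], alive[y], universe_size, **kwargs)

    # Cache of mergeable pairs only; rows touching a merged pathway are
    # re-evaluated, the rest is static.
    mergeable: dict[tuple[str, str], MergeDecision] = {}
    ids = sorted(alive)
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            d = decide(x, y)
            if d.mergeable:
                mergeable[(x, y)] = d

    log: list[MergeEvent] = []
    n_iter = 0
    while mergeable:
        n_iter += 1
        # Highest overlap first; ties go to the lexicographically smaller id pair.
        best = max(mergeable.values(), key=lambda d: d.overlap)
        candidates = sorted(k for k, d in mergeable.items() if d.overlap == best.overlap)
        key = candidates[0]
        d = mergeable[key]
        a, b = alive[key[0]], alive[key[1]]
        survivor, absorbed = _survivor_absorbed(a, b)
        merged = replace(
            survivor,
            genes=survivor.genes | absorbed.genes,
            provenance=tuple(
                dict.fromkeys([*survivor.provenance, absorbed.id, *absorbed.provenance])
            ),
        )
        log.append(
            MergeEvent(
                surviving_id=survivor.id,
                absorbed_id=absorbed.id,
                criterion=d.criterion or "",
                overlap=d.overlap,
            )
        )
        del alive[absorbed.id]
        alive[survivor.id] = merged
        mergeable = {
            k: v for k, v in mergeable.items() if survivor.id not in k and absorbed.id not in k
        }
        for other in alive:
            if other == survivor.id:
                continue
            pair = tuple(sorted((other, survivor.id)))
            nd = decide(*pair)
            if nd.mergeable:
                mergeable[pair] = nd  # type: ignore[index]

    out = PathwayCollection(
        sorted(alive.values(), key=lambda p: order[p.id]), universe=collection.universe
    )
    report = CondensationReport(
        n_input=len(collection), n_output=len(out), merge_log=tuple(log), n_iterations=n_iter
    )
    return out, report


def exclude_small(
    collection: PathwayCollection, min_genes: int = 3
) -> tuple[PathwayCollection, list[str]]:
    """Drop pathways with fewer than ``min_genes`` genes.

    Returns the filtered collection and the list of removed pathway ids.
    Run after condensation by default: criterion 3 needs the small
    pathways still present to absorb them into their supersets.
    """
    if min_genes < 1:
        raise ValidationError("min_genes must be >= 1")
    kept = [p for p in collection if p.n_genes >= min_genes]
    removed = [p.id for p in collection if p.n_genes < min_genes]
    return PathwayCollection(kept, universe=collection.universe), removed
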