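"""Core in-memory containers: pathways, collections, assay annotations, activity calls.

A *pathway* is treated purely as a named gene set; a *collection* is an
ordered list of pathways together with the gene universe used as the
background population for exact tests. Gene identifiers are opaque,
case-sensitive strings (symbols or numeric ids) normalized only by
stripping surrounding whitespace — no symbol-to-id harmonization is
attempted, keeping I/O deterministic and source-agnostic.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import ValidationError


def normalize_gene(gene: str) -> str:
    """Strip surrounding whitespace; reject empty identifiers."""
    g = gene.strip()
    if not g:
        raise ValidationError("empty gene identifier")
    return g


class AssaySource(enum.Enum):
    """Bioassay sources, ordered by decreasing priority.

    When a gene (or pathway) is covered by several sources only the
    highest-priority one is counted: Tox21 first, then other in-house
    (NCATS) assays, then PubChem, then commercial vendors.
    """

    TOX21 = 1
    NCATS = 2
    PUBCHEM = 3
    COMMERCIAL = 4

    @property
    def priority(self) -> int:
        """Smaller is higher priority."""
        return self.value


@dataclass(frozen=True)
class Pathway:
    """A named gene set.

    Parameters
    ----------
    id : unique identifier within a collection.
    name : human-readable title (used by keyword tagging).
    source : label of the originating database, or ``"merged"``.
    genes : the gene components, stored as a frozenset.
    provenance : ids of pathways absorbed into this one by condensation.
    """

    id: str
    name: str
    genes: frozenset[str]
    source: str = "unknown"
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id or self.id != self.id.strip():
            raise ValidationError(f"invalid pathway id {self.id!r}")
        if self.id in self.provenance:
            raise ValidationError(f"pathway {self.id!r} lists itself as provenance")
        object.__setattr__(self, "genes", frozenset(normalize_gene(g) for g in self.genes))

    @property
    def n_genes(self) -> int:
        return len(self.genes)


class PathwayCollection:
    """An ordered set of pathways over a gene universe.

    The universe defaults to the union of all pathway genes and serves as
    the background population N for Fisher's exact tests downstream.
    """

    def __init__(self, pathways: Iterable[Pathway], universe: Iterable[str] | None = None):
        self.pathways: list[Pathway] = list(pathways)
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate pathway id(s): {', '.join(dup)}")
        union: set[str] = set()
        for p in self.pathways:
            union |= p.genes
        if universe is None:
            self.universe: frozenset[str] = frozenset(union)
        else:
            self.universe = frozenset(normalize_gene(g) for g in universe)
            missing = union - self.universe
            if missing:
                raise ValidationError(
                    f"{len(missing)} pathway gene(s) outside the declared universe, "
                    f"e.g. {sorted(missing)[:3]}"
                )

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def __contains__(self, pathway_id: str) -> bool:
        return any(p.id == pathway_id for p in self.pathways)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    def gene_union(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)


@dataclass(frozen=True)
class AssayAnnotation:
    """Assay availability for one gene across the four source tiers."""

    gene: str
    sources: frozenset[AssaySource]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        if not self.sources:
            raise ValidationError(f"gene {self.gene!r} has an empty assay-source set")
        object.__setattr__(self, "sources", frozenset(self.sources))

    @property
    def best_source(self) -> AssaySource:
        """The highest-priority source available for this gene."""
        return min(self.sources, key=lambda s: s.priority)


class ActivityMatrix:
    """Binary compound x assay activity calls from a screening campaign."""

    def __init__(
        self,
        compounds: Sequence[str],
        assays: Sequence[str],
        calls: np.ndarray | Sequence[Sequence[int]],
    ):
        self.compounds = list(compounds)
        self.assays = list(assays)
        if len(set(self.compounds)) != len(self.compounds):
            raise ValidationError("duplicate compound ids")
        if len(set(self.assays)) != len(self.assays):
            raise ValidationError("duplicate assay ids")
        arr = np.asarray(calls)
        if arr.shape != (len(self.compounds), len(self.assays)):
            raise ValidationError(
                f"calls shape {arr.shape} does not match "
                f"{len(self.compounds)} compounds x {len(self.assays)} assays"
            )
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = arr[~np.isin(arr, (0, 1))].flat[0]
            raise ValidationError(f"non-binary activity value {bad!r}")
        self.calls = arr.astype(np.int8).reshape(len(self.compounds), len(self.assays))

    def active_compounds(self, assay: str) -> frozenset[str]:
        """Set of compound ids called active in the given assay."""
        j = self.assays.index(assay)
        mask = self.calls[:, j] == 1
        return frozenset(c for c, m in zip(self.compounds, mask) if m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape  # type: ignore[return-value]


GeneTagMap = Mapping[str, frozenset[str]]
KeywordLexicon = Mapping[str, frozenset[str]]
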