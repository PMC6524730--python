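"""Gene-list pathway enrichment.

For a query gene list, each pathway is tested for over-representation
with a one-sided Fisher's exact test: with universe size N, pathway
size K, effective query size m and overlap k, the p-value is the
hypergeometric upper tail P[X >= k]. Benjamini-Hochberg q-values are
reported across all pathways tested.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from statsmodels.stats.multitest import multipletests

from ._stats import overlap_pvalue
from .errors import EmptyQueryError
from .model import PathwayCollection


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher's exact over-representation result for one pathway."""

    pathway_id: str
    k: int  # overlap between query and pathway
    m: int  # effective query size (after universe intersection)
    K: int  # pathway size within the universe
    N: int  # universe size
    p: float
    q: float


def enrich(
    query: set[str] | frozenset[str],
    collection: PathwayCollection,
    universe: set[str] | frozenset[str] | None = None,
) -> list[EnrichmentResult]:
    """Test every pathway for over-representation of ``query`` genes.

    Query genes outside the universe are dropped with a warning (the
    effective m is what the results report). Results are sorted by
    ascending p, then pathway id.

    Raises
    ------
    EmptyQueryError
        If no query gene lies in the universe.
    """
    uni = frozenset(universe) if universe is not None else collection.universe
    q_eff = frozenset(query) & uni
    dropped = len(set(query)) - len(q_eff)
    if dropped:
        warnings.warn(
            f"{dropped} query gene(s) not in the universe were dropped "
            f"(effective query size {len(q_eff)})",
            stacklevel=2,
        )
    if not q_eff:
        raise EmptyQueryError("query has no genes in the analysis universe")
    N, m = len(uni), len(q_eff)
    records = []
    for p in collection:
        genes = p.genes & uni
        k = len(genes & q_eff)
        pv = overlap_pvalue(k, len(genes), m, N)
        records.append((p.id, k, len(genes), pv))
    _, qvals, _, _ = multipletests([r[3] for r in records], method="fdr_bh")
    results = [
        EnrichmentResult(pathway_id=pid, k=k, m=m, K=K, N=N, p=pv, q=float(qv))
        for (pid, k, K, pv), qv in zip(records, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results
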