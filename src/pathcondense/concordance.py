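"""Compound-activity concordance between pathway assays.

If pathways sharing gene components respond to the same compounds, the
activity overlap of two assays (actives in both over actives in either,
a Jaccard index of active-compound sets) should rise with the gene
sharing of the pathways they probe. This module computes that
relationship over all assay pairs and its correlation, overall and
restricted to pairs whose gene sharing exceeds a threshold (20% by
default).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from scipy import stats

from .errors import (
    DegenerateCorrelationError,
    InsufficientPairsError,
    UndefinedOverlapError,
)
from .model import ActivityMatrix, PathwayCollection
from .similarity import jaccard, similarity


def activity_overlap(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Compounds active in both assays over compounds active in either."""
    if not a and not b:
        raise UndefinedOverlapError("no compound active in either assay")
    return jaccard(a, b)


@dataclass(frozen=True)
class AssayPairRecord:
    """Gene sharing and activity overlap for one unordered assay pair."""

    pair: tuple[str, str]
    gene_sharing: float
    activity_overlap: float


@dataclass(frozen=True)
class ConcordanceResult:
    """Correlation between gene sharing and activity overlap.

    ``r_conditional`` is the same correlation restricted to pairs with
    gene sharing above ``threshold`` (``nan`` when fewer than 3 such
    pairs exist or their sharing has no variance).
    """

    r: float
    p: float
    r_conditional: float
    p_conditional: float
    threshold: float
    n_pairs: int
    n_pairs_conditional: int
    n_excluded: int
    records: tuple[AssayPairRecord, ...]
    method: str = "pearson"


def _corr(x: list[float], y: list[float], method: str) -> tuple[float, float]:
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def sharing_activity_correlation(
    matrix: ActivityMatrix,
    assay_pathways: Mapping[str, str],
    collection: PathwayCollection,
    *,
    threshold: float = 0.2,
    method: str = "pearson",
) -> ConcordanceResult:
    """Correlate per-pair gene sharing with per-pair activity overlap.

    Every unordered assay pair contributes one point; pairs with no
    active compound in either assay are excluded (counted in
    ``n_excluded``). Requires >=3 usable pairs and non-zero variance in
    both variables.
    """
    missing = [a for a in matrix.assays if a not in assay_pathways]
    if missing:
        raise KeyError(f"assay(s) without a pathway mapping: {missing[:5]}")
    for a, pid in assay_pathways.items():
        if a in matrix.assays and pid not in collection:
            raise KeyError(f"assay {a!r} maps to unknown pathway {pid!r}")

    actives = {a: matrix.active_compounds(a) for a in matrix.assays}
    records: list[AssayPairRecord] = []
    n_excluded = 0
    assays = matrix.assays
    for i, a in enumerate(assays):
        for b in assays[i + 1 :]:
            if not actives[a] and not actives[b]:
                n_excluded += 1
                continue
            s = similarity(collection[assay_pathways[a]], collection[assay_pathways[b]])
            records.append(
                AssayPairRecord(
                    pair=(a, b),
                    gene_sharing=s,
                    activity_overlap=activity_overlap(actives[a], actives[b]),
                )
            )
    if len(records) < 3:
        raise InsufficientPairsError(f"only {len(records)} usable assay pair(s); need >= 3")
    x = [r.gene_sharing for r in records]
    y = [r.activity_overlap for r in records]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise DegenerateCorrelationError("zero variance in gene sharing or activity overlap")
    r, p = _corr(x, y, method)

    cond = [rec for rec in records if rec.gene_sharing > threshold]
    if len(cond) >= 3 and len({c.gene_sharing for c in cond}) > 1 and len(
        {c.activity_overlap for c in cond}
    ) > 1:
        r_c, p_c = _corr(
            [c.gene_sharing for c in cond], [c.activity_overlap for c in cond], method
        )
    else:
        r_c, p_c = math.nan, math.nan

    return ConcordanceResult(
        r=r,
        p=p,
        r_conditional=r_c,
        p_conditional=p_c,
        threshold=threshold,
        n_pairs=len(records),
        n_pairs_conditional=len(cond),
        n_excluded=n_excluded,
        records=tuple(records),
        method=method,
    )
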