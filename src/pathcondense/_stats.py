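"""Shared exact-test helper."""
from __future__ import annotations

from scipy.stats import hypergeom


def overlap_pvalue(k: int, size_a: int, size_b: int, universe: int) -> float:
    """One-sided Fisher's exact p for observing >=k shared genes.

    The 2x2 table classifies the ``universe`` genes by membership in A
    (margin ``size_a``) and in B (margin ``size_b``); the one-sided
    over-enrichment p equals the upper hypergeometric tail
    P[X >= k] with X ~ Hypergeom(universe, size_a, size_b).
    """
    if k < 0 or size_a < 0 or size_b < 0:
        raise ValueError("negative table entry")
    if size_a > universe or size_b > universe or k > min(size_a, size_b):
        raise ValueError(f"inconsistent table: k={k}, |A|={size_a}, |B|={size_b}, N={universe}")
    # sf(k-1) = P[X >= k]
    return float(min(1.0, hypergeom.sf(k - 1, universe, size_a, size_b)))
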