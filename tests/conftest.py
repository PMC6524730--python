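from __future__ import annotations

import math

import pytest
from hypothesis import settings

from pathcondense.model import Pathway, PathwayCollection
from pathcondense.synth import SynthConfig, generate_collection

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def P(pid: str, *genes: str, name: str | None = None, source: str = "test") -> Pathway:
    """Shorthand pathway constructor for tests."""
    return Pathway(id=pid, name=name or pid, genes=frozenset(genes), source=source)


@pytest.fixture
def make_pathway():
    return P


@pytest.fixture(scope="session")
def planted_bundle():
    """Default planted-redundancy collection and its ledger (seed 0)."""
    return generate_collection(SynthConfig(seed=0))


def hypergeom_tail(k: int, K: int, m: int, N: int) -> float:
    """Independent oracle: P[X >= k] by direct summation of the
    hypergeometric pmf with exact integer binomials."""
    denom = math.comb(N, m)
    return sum(math.comb(K, i) * math.comb(N - K, m - i) for i in range(k, min(K, m) + 1)) / denom
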