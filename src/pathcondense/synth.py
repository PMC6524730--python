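"""Seeded synthetic pathway collections and screening data with known truth.

The generator emulates the redundancy structure of a multi-source
pathway compendium: a set of ground-truth *base* pathways plus planted
redundant variants of four classes — exact duplicates, near-duplicates
(similarity above 0.9), one-gene-difference variants, and tiny (1-2
gene) subset pathways. A ground-truth ledger records, for every planted
pathway, its base, its class, and the merge criterion its relation is
expected to trigger, so condensation can be scored exactly.

It also emits compound x assay activity matrices under a single-latent-
target model: each compound is assigned a target gene; it is active in
an assay with probability ``baseline_rate``, raised by
``sharing_effect`` when its target belongs to the assay's pathway.
Assays probing gene-sharing pathways therefore share actives, which is
the premise the concordance analysis tests. Setting ``sharing_effect``
to 0 gives the null model.

All sampling is driven by ``numpy.random.default_rng`` on the
configured seed, so identical configurations reproduce identical data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleConfigError
from .model import ActivityMatrix, Pathway, PathwayCollection
from .panel import BRUTE_FORCE_MAX_GENES, brute_force_cover

PLANT_CLASSES = ("base", "exact_dup", "near_dup", "one_off", "small_subset")


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic generator.

    Defaults describe the standard study conditions used throughout the
    test-suite: 100 base pathways of 5-40 genes over a 1,000-gene
    universe with 15 planted pathways of each redundancy class, and
    screening of 2,000 compounds at a 2% baseline hit rate with a 0.5
    activity boost for on-target assays.
    """

    seed: int = 0
    n_base: int = 100
    universe_size: int = 1000
    size_range: tuple[int, int] = (5, 40)
    n_exact_dup: int = 15
    n_near_dup: int = 15
    n_one_off: int = 15
    n_small_subset: int = 15
    tag_structure: Mapping[str, float] = field(default_factory=dict)
    n_pathways_per_tag: int = 5
    n_compounds: int = 2000
    baseline_rate: float = 0.02
    sharing_effect: float = 0.5
    n_targets_per_compound: int = 1

    def __post_init__(self) -> None:
        counts = (
            self.n_base,
            self.n_exact_dup,
            self.n_near_dup,
            self.n_one_off,
            self.n_small_subset,
            self.n_compounds,
            self.n_targets_per_compound,
        )
        if any(c < 0 for c in counts):
            raise InfeasibleConfigError("counts must be non-negative")
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise InfeasibleConfigError(f"size_range {self.size_range} invalid (min >= 3 required)")
        if hi > self.universe_size:
            raise InfeasibleConfigError("base pathways cannot exceed the universe")
        if not (0.0 <= self.baseline_rate <= 1.0) or not (0.0 <= self.sharing_effect <= 1.0):
            raise InfeasibleConfigError("rates must lie in [0, 1]")
        for tag, frac in self.tag_structure.items():
            if not (0.0 < frac <= 1.0):
                raise InfeasibleConfigError(f"tag fraction for {tag!r} must be in (0, 1]")

    @property
    def n_variants(self) -> int:
        return self.n_exact_dup + self.n_near_dup + self.n_one_off + self.n_small_subset


@dataclass(frozen=True)
class GroundTruthLedger:
    """What the generator planted, for use as a test oracle."""

    base_of: dict[str, str]  # variant id -> base id
    planted_class: dict[str, str]  # pathway id -> class
    expected_criterion: dict[str, str]  # variant id -> "c1".."c4"
    planted_tags: dict[str, frozenset[str]]  # pathway id -> tags
    gene_tags: dict[str, frozenset[str]]  # gene -> tags (input for tagging)
    true_min_cover_size: int | None


def _expected_criterion(base: frozenset[str], variant: frozenset[str]) -> str:
    """The merge criterion a planted pair triggers, by the rule precedence
    (overlap > 90%, then one-gene difference, then small subset)."""
    inter = len(base & variant)
    union = len(base | variant)
    s = inter / union
    if s > 0.9:
        return "c1"
    if union - inter == 1:
        return "c2"
    small = min(len(base), len(variant))
    if small < 3 and (base <= variant or variant <= base):
        return "c3"
    raise AssertionError("planted relation does not match any analytic criterion")


def generate_collection(cfg: SynthConfig) -> tuple[PathwayCollection, GroundTruthLedger]:
    """Generate a collection with planted redundancy and its ledger.

    Every variant is planted on a *distinct* base pathway, so the
    condensation fixpoint of the emitted collection is exactly the base
    set. Near-duplicates are planted on bases of >= 10 genes (smaller
    sets cannot realize a strict 0.9-1 similarity band) and one-gene
    variants on bases of <= 9 genes (so their pair is *not* already
    above the 90% overlap bar); base sizes are adjusted to guarantee
    enough eligible bases.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_variants > cfg.n_base:
        raise InfeasibleConfigError(
            f"{cfg.n_variants} variants need {cfg.n_variants} distinct bases, have {cfg.n_base}"
        )
    lo, hi = cfg.size_range
    if cfg.n_near_dup and hi < 10:
        raise InfeasibleConfigError("near-duplicates need bases of >= 10 genes")
    universe = [f"G{i:05d}" for i in range(cfg.universe_size)]
    universe_set = frozenset(universe)

    sizes = rng.integers(lo, hi + 1, size=cfg.n_base)
    order = list(rng.permutation(cfg.n_base))
    # Reserve eligible bases per class, resizing if the draw fell short.
    need_small = cfg.n_one_off if lo <= 9 else 0
    assign: dict[str, list[int]] = {"exact_dup": [], "near_dup": [], "one_off": [], "small_subset": []}
    remaining = order[:]

    def take(cls: str, count: int, pred, resize) -> None:
        chosen = [i for i in remaining if pred(sizes[i])][:count]
        shortfall = count - len(chosen)
        if shortfall:
            extra = [i for i in remaining if i not in chosen][:shortfall]
            if len(extra) < shortfall:
                raise InfeasibleConfigError(f"not enough bases for class {cls}")
            for i in extra:
                sizes[i] = resize()
            chosen += extra
        assign[cls] = chosen
        for i in chosen:
            remaining.remove(i)

    take("near_dup", cfg.n_near_dup, lambda n: n >= 10, lambda: int(rng.integers(max(lo, 10), hi + 1)))
    if need_small:
        take("one_off", cfg.n_one_off, lambda n: n <= 9, lambda: int(rng.integers(lo, 10)))
    else:
        take("one_off", cfg.n_one_off, lambda n: True, lambda: int(rng.integers(lo, hi + 1)))
    take("exact_dup", cfg.n_exact_dup, lambda n: True, lambda: int(rng.integers(lo, hi + 1)))
    take("small_subset", cfg.n_small_subset, lambda n: n >= 3, lambda: int(rng.integers(max(lo, 3), hi + 1)))

    sources = ("alpha", "beta", "gamma")
    bases: list[Pathway] = []
    for i in range(cfg.n_base):
        genes = frozenset(map(str, rng.choice(universe, size=int(sizes[i]), replace=False)))
        bases.append(
            Pathway(
                id=f"B{i:04d}",
                name=f"Synthetic process {i}",
                genes=genes,
                source=sources[i % len(sources)],
            )
        )

    used = set().union(*(p.genes for p in bases)) if bases else set()

    def fresh_genes(count: int, avoid: frozenset[str]) -> list[str]:
        pool = sorted(universe_set - used)
        if len(pool) < count:
            pool = sorted(universe_set - avoid)
        if len(pool) < count:
            raise InfeasibleConfigError("universe too small to plant variant genes")
        picked = [str(g) for g in rng.choice(pool, size=count, replace=False)]
        used.update(picked)
        return picked

    variants: list[Pathway] = []
    base_of: dict[str, str] = {}
    planted_class: dict[str, str] = {p.id: "base" for p in bases}
    expected: dict[str, str] = {}
    counter = 0
    for cls, idxs in assign.items():
        for i in idxs:
            base = bases[i]
            counter += 1
            vid = f"V{counter:04d}"
            if cls == "exact_dup":
                genes = base.genes
            elif cls == "near_dup":
                # target similarity drawn from (0.9, 1): add a extra genes
                # with n/(n+a) > 0.9
                a_max = (base.n_genes - 1) // 9
                target_s = rng.uniform(0.9, 1.0)
                a = int(round(base.n_genes * (1 - target_s) / target_s))
                a = min(max(a, 1), max(a_max, 1))
                genes = base.genes | frozenset(fresh_genes(a, base.genes))
            elif cls == "one_off":
                if base.n_genes > lo and rng.random() < 0.5:
                    drop = str(rng.choice(sorted(base.genes)))
                    genes = base.genes - {drop}
                else:
                    genes = base.genes | frozenset(fresh_genes(1, base.genes))
            else:  # small_subset
                k = int(rng.integers(1, min(3, base.n_genes)))
                genes = frozenset(map(str, rng.choice(sorted(base.genes), size=k, replace=False)))
            variants.append(
                Pathway(
                    id=vid,
                    name=f"{base.name} (variant)",
                    genes=genes,
                    source=sources[(i + 1) % len(sources)],
                )
            )
            base_of[vid] = base.id
            planted_class[vid] = cls
            expected[vid] = _expected_criterion(base.genes, genes)

    pathways = bases + variants
    perm = rng.permutation(len(pathways))
    collection = PathwayCollection([pathways[int(j)] for j in perm], universe=universe)

    _assert_planted_relations(collection, base_of, planted_class)

    planted_tags, gene_tags = _plant_tags(cfg, rng, bases, base_of, collection)

    true_min = None
    if len(collection.gene_union()) <= BRUTE_FORCE_MAX_GENES:
        true_min = brute_force_cover(collection).n_selected

    ledger = GroundTruthLedger(
        base_of=base_of,
        planted_class=planted_class,
        expected_criterion=expected,
        planted_tags=planted_tags,
        gene_tags=gene_tags,
        true_min_cover_size=true_min,
    )
    return collection, ledger


def _assert_planted_relations(
    collection: PathwayCollection, base_of: Mapping[str, str], planted_class: Mapping[str, str]
) -> None:
    """Ledger fidelity check: every planted relation holds exactly."""
    for vid, bid in base_of.items():
        v, b = collection[vid].genes, collection[bid].genes
        cls = planted_class[vid]
        inter, union = len(v & b), len(v | b)
        if cls == "exact_dup":
            assert v == b
        elif cls == "near_dup":
            assert v != b and inter / union > 0.9
        elif cls == "one_off":
            assert union - inter == 1
        elif cls == "small_subset":
            assert len(v) < 3 and v <= b


def _plant_tags(
    cfg: SynthConfig,
    rng: np.random.Generator,
    bases: Sequence[Pathway],
    base_of: Mapping[str, str],
    collection: PathwayCollection,
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Plant gene->tag structure so chosen pathways pass the 10%/>=4 rule.

    Tags are planted only on bases without variants, preferring genes
    shared with as few other pathways as possible; a verification pass
    then confirms that the rule recovers exactly the planted
    assignments (no leakage into other pathways).
    """
    if not cfg.tag_structure:
        return {}, {}
    with_variants = set(base_of.values())
    free = [b for b in bases if b.id not in with_variants]
    gene_count: dict[str, int] = {}
    for p in collection:
        for g in p.genes:
            gene_count[g] = gene_count.get(g, 0) + 1
    planted: dict[str, set[str]] = {}
    gene_tags: dict[str, set[str]] = {}
    for tag in sorted(cfg.tag_structure):
        frac = cfg.tag_structure[tag]
        candidates = [b for b in free if b.n_genes >= max(4, math.ceil(frac * b.n_genes))]
        if len(candidates) < cfg.n_pathways_per_tag:
            raise InfeasibleConfigError(
                f"cannot plant tag {tag!r}: only {len(candidates)} eligible pathways"
            )
        chosen = rng.choice(len(candidates), size=cfg.n_pathways_per_tag, replace=False)
        for ci in sorted(int(c) for c in chosen):
            b = candidates[ci]
            k = max(4, math.ceil(frac * b.n_genes))
            by_sharing = sorted(b.genes, key=lambda g: (gene_count[g], g))
            for g in by_sharing[:k]:
                gene_tags.setdefault(g, set()).add(tag)
            planted.setdefault(b.id, set()).add(tag)
    # Verification: the 10%/>=4 rule over the emitted collection must
    # recover the planted assignments exactly.
    recovered: dict[str, set[str]] = {}
    for p in collection:
        counts: dict[str, int] = {}
        for g in p.genes:
            for t in gene_tags.get(g, ()):
                counts[t] = counts.get(t, 0) + 1
        hits = {t for t, n in counts.items() if n >= 4 and n / p.n_genes >= 0.10}
        if hits:
            recovered[p.id] = hits
    if recovered != planted:
        raise InfeasibleConfigError(
            "planted tag structure leaks into other pathways at this seed; "
            "use a different seed or fewer/lower tag fractions"
        )
    return (
        {k: frozenset(v) for k, v in planted.items()},
        {k: frozenset(v) for k, v in gene_tags.items()},
    )


def generate_activity(
    cfg: SynthConfig,
    assay_pathways: Mapping[str, str],
    collection: PathwayCollection,
) -> ActivityMatrix:
    """Simulate a binary compound x assay screen under the latent-target model.

    Each compound receives ``n_targets_per_compound`` latent target
    gene(s) drawn uniformly from the collection universe; its activity
    probability in an assay is ``baseline_rate`` plus ``sharing_effect``
    if any target lies in the assay's pathway, clipped to [0, 1].
    """
    for a, pid in assay_pathways.items():
        if pid not in collection:
            raise KeyError(f"assay {a!r} maps to unknown pathway {pid!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 0x5EED)))
    assays = list(assay_pathways)
    universe = sorted(collection.universe)
    compounds = [f"C{i:05d}" for i in range(cfg.n_compounds)]
    if not compounds or not assays:
        return ActivityMatrix(compounds, assays, np.zeros((len(compounds), len(assays)), dtype=np.int8))
    targets = rng.choice(len(universe), size=(cfg.n_compounds, cfg.n_targets_per_compound))
    gene_pos = {g: i for i, g in enumerate(universe)}
    pathway_masks = np.zeros((len(assays), len(universe)), dtype=bool)
    for j, a in enumerate(assays):
        for g in collection[assay_pathways[a]].genes:
            pathway_masks[j, gene_pos[g]] = True
    # hit[i, j] = any latent target of compound i in pathway of assay j
    hit = pathway_masks[:, targets].any(axis=2).T  # (n_compounds, n_assays)
    prob = np.clip(cfg.baseline_rate + cfg.sharing_effect * hit, 0.0, 1.0)
    calls = (rng.random(prob.shape) < prob).astype(np.int8)
    return ActivityMatrix(compounds, assays, calls)


def overlapping_windows_collection(
    n_pathways: int = 25, window: int = 25, stride: int = 8
) -> PathwayCollection:
    """A deterministic chain of gene-sharing pathways.

    Pathway ``i`` holds genes ``[i*stride, i*stride + window)`` of a
    linear gene list, so adjacent pathways share ``window - stride``
    genes and sharing decays with chain distance — a graded sharing
    structure for concordance studies (no randomness involved). The
    default geometry gives several distinct sharing levels, two of them
    above the 20% conditional-analysis threshold.
    """
    if n_pathways < 1 or window < 1 or stride < 1:
        raise InfeasibleConfigError("n_pathways, window and stride must be positive")
    n_genes = (n_pathways - 1) * stride + window
    genes = [f"G{i:05d}" for i in range(n_genes)]
    pathways = [
        Pathway(
            id=f"W{i:03d}",
            name=f"Window process {i}",
            genes=frozenset(genes[i * stride : i * stride + window]),
            source="windows",
        )
        for i in range(n_pathways)
    ]
    return PathwayCollection(pathways, universe=genes)


def concordance_scenario(
    seed: int,
    *,
    n_assays: int = 25,
    sharing_effect: float = 0.5,
    baseline_rate: float = 0.02,
    n_compounds: int = 2000,
) -> tuple[PathwayCollection, dict[str, str], ActivityMatrix]:
    """Standard concordance study: window pathways, one assay per pathway.

    Returns the pathway collection, the assay -> pathway map, and the
    simulated activity matrix.
    """
    collection = overlapping_windows_collection(n_pathways=n_assays)
    assay_map = {f"assay_{p.id}": p.id for p in collection}
    cfg = SynthConfig(
        seed=seed,
        n_compounds=n_compounds,
        baseline_rate=baseline_rate,
        sharing_effect=sharing_effect,
    )
    matrix = generate_activity(cfg, assay_map, collection)
    return collection, assay_map, matrix
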