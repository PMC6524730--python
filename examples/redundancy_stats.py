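"""Measure how redundant a pathway compendium is before condensation.

For every pathway, finds its best-matching partner by gene-component
similarity (shared genes over total unique genes) and summarizes the
duplicate structure and the size distribution.
"""
from pathcondense import SynthConfig, generate_collection, redundancy_stats

collection, _ = generate_collection(SynthConfig(seed=1))
stats = redundancy_stats(collection)

print(f"pathways: {len(collection)}")
print(f"with an exact duplicate (best match s = 1):    {stats.frac_exact_duplicate:.1%}")
print(f"with a close match (best match s > 0.9):       {stats.frac_close_match:.1%}")
print(f"with <= 5 genes: {stats.frac_le5:.1%};  single-gene: {stats.frac_single_gene:.1%}")
print("size histogram (genes -> pathways):")
for bin_, count in stats.size_histogram.items():
    if count:
        print(f"  {bin_:>7}: {count}")
# High duplicate fractions mean the collection double-counts biology;
# condensation removes exactly this redundancy.
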