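"""Lay pathways out on a sphere so distance mirrors dissimilarity.

Target geodesic distance between two pathways is (1 - similarity) * pi:
identical pathways coincide, disjoint ones sit antipodal. A monotone
projected-gradient descent minimizes normalized stress between realized
and target great-circle distances.
"""
from pathcondense import SynthConfig, condense_collection, embed_sphere, generate_collection
from pathcondense.globe import geodesic

collection, _ = generate_collection(
    SynthConfig(seed=1, n_base=40, n_exact_dup=5, n_near_dup=5, n_one_off=0, n_small_subset=0)
)
layout = embed_sphere(collection, seed=17, n_iterations=300)
print(f"embedded {len(layout.coordinates)} pathways on the unit sphere")
print(f"stress: initial {layout.stress_history[0]:.4f} -> final {layout.stress:.4f} "
      f"after {layout.n_iterations} accepted steps")

# planted duplicates must land together
merged, report = condense_collection(collection)
ev = report.merge_log[0]
d = geodesic(layout.coordinates[ev.surviving_id], layout.coordinates[ev.absorbed_id])
print(f"redundant pair {ev.surviving_id}/{ev.absorbed_id} "
      f"(overlap {ev.overlap:.2f}): geodesic distance {d:.3f} rad")

lat, lon = layout.latlon_degrees()[ev.surviving_id]
print(f"{ev.surviving_id} plots at latitude {lat:.1f}, longitude {lon:.1f}")
# Stress near 0.5-0.8 is expected for many mutually disjoint pathways
# (they cannot all be antipodal); what matters is that similar pathways
# sit close while unrelated ones are pushed far apart.
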