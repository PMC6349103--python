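"""Skeleton distribution statistics over a genus/clade taxonomy.

Generates a seeded synthetic occurrence dataset (decorated compounds,
genus/clade taxonomy, multi-source occurrence rows), extracts skeletons,
and computes the chemotaxonomic marginals: per-skeleton genus/clade
spread, per-genus diversity, database overlap, and the set of skeletons
not reachable by a table of known enzyme products.
"""

import pandas as pd

from skeletax import (
    GeneratorConfig,
    database_overlap,
    default_library,
    extract_skeleton,
    generate_compounds,
    generate_occurrence,
    generate_taxonomy,
    skeleton_distribution,
    unknown_route_skeletons,
)

cfg = GeneratorConfig(seed=7, n_compounds=80, occurrence_density=0.03)
library = default_library()
records, truth = generate_compounds(cfg, library)
taxonomy, clade_map = generate_taxonomy(cfg)
occurrence, _ = generate_occurrence(cfg, records, taxonomy, clade_map)
assignments = {r.compound_id: extract_skeleton(r, library) for r in records}

dist = skeleton_distribution(
    occurrence, assignments, structure_sources=["DNP-like", "SISTEMAT-like"]
)
summary = dist.per_skeleton.copy()
names = {
    a.skeleton.skeleton_id: a.skeleton.reference_name
    for a in assignments.values()
}
summary["reference_name"] = summary["skeleton_id"].map(names)
summary["skeleton_id"] = summary["skeleton_id"].str.slice(0, 18) + "..."
print("Per-skeleton distribution (how many compounds carry each skeleton,")
print("and in how many genera / how many of the 12 clades it is reported):")
print(summary.to_string(index=False))

# which observed skeletons lack a known biosynthetic route?
known_products = pd.DataFrame(
    {
        "enzyme": ["CPS-like", "KS-like"],
        "product": ["labdadienyl-PP", "kaurene"],
        "product_skeleton": ["Sk4 labdane", "Sk1 kaurane"],
    }
)
unknown = unknown_route_skeletons(dist, known_products, library)
print(
    f"\n{len(dist.observed_skeletons())} skeletons observed; with known "
    f"routes to Sk4/Sk1 cores, {len(unknown)} remain without a route."
)

overlap = database_overlap(occurrence)
pair = overlap[
    (overlap["source_a"] == "DNP-like")
    & (overlap["source_b"] == "SISTEMAT-like")
]
print(
    f"\nDNP-like vs SISTEMAT-like per-genus overlap "
    f"(first 5 of {len(pair)} genera):"
)
print(pair.head(5).to_string(index=False))
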