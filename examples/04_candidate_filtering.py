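"""Homology-hit filtering and identity-based peptide merging.

Generates a seeded tabular hit table, applies the candidate rule (keep a
subject iff its best-bitscore hit shows >= 35% identity and >= 70% query
coverage), then merges near-identical peptides at 95% global identity by
greedy length-descending clustering.
"""

from skeletax import (
    FilterConfig,
    GeneratorConfig,
    HomologyHit,
    filter_candidates,
    generate_hits,
    generate_peptides,
    greedy_cluster,
)
from skeletax.candidate_filter import clusters_table

cfg = GeneratorConfig(seed=11, n_subjects=40)
table, query_lengths, _ = generate_hits(cfg)
hits = [
    HomologyHit(
        query_id=r.query_id, subject_id=r.subject_id,
        percent_identity=r.percent_identity,
        alignment_length=r.alignment_length,
        q_start=r.q_start, q_end=r.q_end, s_start=r.s_start, s_end=r.s_end,
        evalue=r.evalue, bitscore=r.bitscore,
        query_length=query_lengths[r.query_id],
    )
    for r in table.itertuples(index=False)
]
result = filter_candidates(hits, FilterConfig(min_identity=35.0,
                                              min_coverage=70.0))
n_kept = int(result["retained"].sum())
print(f"{n_kept}/{len(result)} subjects pass the 35%/70% rule; "
      "closest calls:")
result["margin"] = (result["identity"] - 35.0).clip(lower=0) + (
    result["coverage"] - 70.0
).clip(lower=0)
print(
    result[result["retained"]]
    .nsmallest(3, "margin")
    .drop(columns="margin")
    .to_string(index=False)
)

seqs, _ = generate_peptides(n_families=4, members_per_family=4, length=80,
                            seed=11)
clusters = greedy_cluster(seqs, threshold=95.0)
print(f"\n{len(seqs)} peptides merge into {len(clusters)} clusters at 95% "
      "identity:")
print(clusters_table(clusters).to_string(index=False))
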