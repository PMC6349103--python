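# skeletax

Carbon-skeleton chemotaxonomy of terpenoid natural products.

Natural-product occurrence databases describe tens of thousands of plant
diterpenoids, but the decorated structures obscure their biosynthetic
origins.  The carbon **skeleton** — the core alkane left after discarding
heteroatoms, bond orders, substituent fragments and stereochemistry — often
resembles the diterpene synthase (diTPS) product far more closely than any
downstream metabolite does.  Mapping skeleton occurrence onto a genus/clade
taxonomy therefore points directly at which lineages must harbor
uncharacterized enzymes.  `skeletax` is a toolkit for that style of
database-driven analysis, aimed at natural-product and enzyme-discovery
researchers:

* **Skeleton extraction** — saturate every bond, break every bond touching a
  non-carbon atom, keep the fragment with carbon count closest to 20
  (configurable for other terpene classes).  Ties are resolved by a
  deterministic rule (more rings, more carbons, smaller canonical ID), are
  flagged for review, and can be overridden per compound — a
  machine-assisted version of manual curation.
* **Canonical skeleton identity** — two cores get the same ID iff their
  unlabeled graphs are isomorphic (realized as the canonical SMILES of the
  saturated hydrocarbon), enabling deduplication and cross-database
  comparison.  A reference library ships with the classic diterpene
  skeletons (kaurane, clerodane, abietane, labdane, pimarane, atisane) and
  their position numbering 1–20.
* **Chemotaxonomy** — taxon-name resolution (exact → normalized → fuzzy with
  review flags), genus→clade assignment over the 12 primary Lamiaceae
  clades, per-skeleton genus/clade distribution statistics, per-genus
  database overlap, and the set difference between observed skeletons and
  those reachable by known enzyme products.
* **Positional pattern queries** — count compounds whose original structure
  carries, say, a 7,8 double bond or a 4(18) epoxide at numbered skeleton
  positions, with existential semantics over skeleton automorphisms
  (solid constraint = exact bond type; dashed = anything).
* **Candidate filtering** — parse 12-column tabular homology-search output,
  keep subjects whose best-bitscore hit shows ≥ 35 % identity and ≥ 70 %
  query coverage (inclusive), and merge peptides at ≥ 95 % global identity
  by greedy length-descending clustering with a deterministic affine-gap
  aligner.
* **Synthetic data** — seeded generators for decorated compound libraries
  with ground-truth skeleton labels, genus/clade taxonomies, occurrence
  tables and hit tables, so every stage is testable without access to
  proprietary databases.

## Worked example

```python
from skeletax import (CompoundRecord, default_library, extract_skeleton,
                      parse_structure, standardize)

sclareol = "CC1(C)CCCC2(C)C1CCC(C)(O)C2CCC(C)(O)C=C"
record = CompoundRecord("sclareol",
                        graph=standardize(parse_structure(sclareol)))
a = extract_skeleton(record, default_library())
print(a.skeleton.carbon_count, a.skeleton.reference_name)
print(a.fragment_carbon_counts)
```

prints

```
20 Sk4 labdane
[20]
```

— sclareol's two hydroxyls are stripped, the single C20 fragment survives,
and its saturated carbon graph is isomorphic to the labdane reference.  A
glycosylated, acetylated labdanoid instead fragments into `[2, 6, 20]`
(acetate, sugar, core) and still resolves to `Sk4 labdane`, because the
C2/C6 fragments lose the closest-to-20 contest
(`examples/01_extract_skeletons.py` shows this end to end, and the other
`examples/` scripts walk the distribution statistics, pattern queries,
candidate filtering and dataset simulation).

A thin CLI mirrors the file-level workflows:

```bash
skeletax simulate --out-dir demo --seed 5 --n-compounds 50
skeletax extract --in demo/compounds.smi --format smiles --out skeletons.csv
skeletax filter --hits demo/hits.tsv --queries queries.fasta --out kept.csv
skeletax merge --in demo/peptides.fasta --out clusters.tsv
```

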