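# Methods

## The skeleton model

A compound's *skeleton* is the graph obtained by (1) setting every bond
order to 1, (2) deleting every bond with at least one non-carbon endpoint,
(3) deleting the non-carbon atoms, and (4) keeping the connected carbon
fragment whose size is closest to a target count (20 for diterpenes).  The
model deliberately ignores stereochemistry: the large occurrence databases
mostly lack stereo annotations, and skeleton identity is meant to group
normal/*ent*/*syn* series together.  Norditerpene cores (C19 and below) are
*distinct* skeletons: a C19 graph is never isomorphic to a C20 graph, which
matches how nor-skeletons are tabulated separately in chemotaxonomic
surveys.

Fragment selection needs a tie rule because |C − 20| can tie (e.g. C18 vs
C22).  The original curation resolved such cases by hand; reproducibility
requires determinism, so the implementation orders ties by (more rings,
then more carbons, then lexicographically smaller canonical ID), flags any
assignment where the winner and runner-up distances differ by at most
`margin` (default 0, i.e. exact ties), and accepts a per-compound override
table mapping `compound_id` to a chosen fragment's canonical ID.  The
flags plus overrides reproduce the "manually examined and corrected"
step as machine-assisted review.  Carbons bonded only to heteroatoms (e.g.
a carbonate carbon) become C1 fragments; they are eligible but can only
win when they are the only fragment.

Carbon conservation — fragment sizes summing to the molecule's carbon
count — is asserted inside `saturate_and_fragment` on every call.

## Canonical identity

Skeleton identity is unlabeled-graph isomorphism.  It is realized as the
canonical SMILES (RDKit) of the saturated hydrocarbon rebuilt from the
fragment; canonical SMILES equality is used as the identity everywhere,
and the test suite enforces the contract (equality ⇔ isomorphism) against
an independent VF2 check (networkx) on random graphs up to 16 carbons,
plus invariance under 500 random relabelings of the library skeletons.
Any canonical labeling scheme with the same soundness/completeness
property could be substituted.

The shipped library encodes kaurane, clerodane, abietane, labdane,
pimarane and atisane as edge lists over the conventional diterpene
numbering (positions 1–20 map to atom indices 0–19).  All six share the
decalin A/B core; they differ in C/D-ring closure and methyl placement,
and are pairwise non-isomorphic (verified in tests).

## Structure handling

Parsing and standardization are delegated to RDKit.  The internal graph
form stores only elements, formal charges and bond orders, with implicit
hydrogens — stereo and isotopes cannot survive the boundary, which is the
intended normalization.  Aromatic systems are fixed to a deterministic
Kekulé assignment during standardization; skeleton extraction saturates
everything anyway, so the choice only matters to positional pattern
queries, which are scoped to non-aromatic ring positions of the reference
skeletons.  Multi-component inputs (salts, mixtures) stay one graph with
several components; component selection happens naturally at fragment
selection.  Formal charges are retained on atoms but never consulted by
skeleton or pattern logic.  Records that fail to parse are logged and
skipped in batch readers rather than aborting a pipeline; strict mode is
available.

## Taxon names and clades

Raw organism names resolve in three stages with strict preference: exact
byte-for-byte match, match on normalized names (lowercase, collapsed
whitespace, parenthesized synonym blocks and rank markers stripped, first
two tokens kept, trailing authority abbreviations dropped), then fuzzy
match by normalized edit similarity, 1 − d/max(len) with Levenshtein d
(edlib).  The fuzzy threshold defaults to 0.9 and fuzzy hits carry a
review flag — mechanizing what was historically manual inspection while
keeping a human channel.  Species records resolve through their parent
genus for clade assignment; genus-level acceptance when species-level
fails is deliberate, mirroring how genus-level taxon IDs are usually
attainable even when species-level ones are not.  Clade assignment is a
case-insensitive lookup into a genus→clade table over the closed set of
12 primary Lamiaceae clades; the shipped fixture covers genera discussed
in this package's documentation, and users supply fuller maps as CSV.
Clade-count denominators are fixed at 12 regardless of how many clades a
dataset happens to touch.

## Distribution statistics

The occurrence table is the deduplicated union of per-source
(compound, taxon) tables, tagged by source; rows with unresolvable taxa
are excluded and counted in the log.  Per-skeleton rows report distinct
compounds, genera and clades; per-genus rows report distinct compounds
(all sources), distinct skeletons (structure-bearing sources only) and
per-source compound counts.  Name-only sources (NAPRALERT-style) identify
compounds by name; the name serves as the compound key, participates in
per-genus structure counts and database overlap, and is excluded from
skeleton statistics — the "each unique name is a unique compound"
simplification.  Database overlap reports per-genus pairwise source
counts and intersection sizes on the compound key.

## Pattern queries

A positional query is scoped to one numbered reference skeleton and
carries constraints of kind `double_bond(p, q)` or `epoxide_bridge(p, q)`
at position pairs, each solid (exact requirement) or dashed (wildcard,
equivalent to no constraint).  A compound matches iff its extracted
skeleton is isomorphic to the scoped reference **and** at least one
isomorphism mapping makes every solid constraint true in the original
standardized structure: order-2 bond between the mapped atoms for
`double_bond`; an order-1 bond plus a shared single-bonded oxygen
neighbor (the three-membered ring) for `epoxide_bridge`.  Existential
semantics over automorphisms means a compound counts once no matter how
many mappings succeed.  This resolves positional ambiguity the permissive
way; the alternative (universal semantics) would undercount on symmetric
skeletons, and nothing in the source material specifies the choice.  The
shipped queries encode Δ7 labdane, Δ8(9) labdane, Δ3 clerodane, Δ4(18)
clerodane and 4(18)-epoxy clerodane; they are plain data (YAML-editable).

## Candidate filtering and merging

Hit tables are the standard 12-column tab-separated dialect; query
lengths are joined from FASTA.  "Most similar query" for a subject is
the highest-bitscore hit (ties: higher identity, then lexicographic query
id).  The subject survives iff that hit has identity ≥ 35 % and query
coverage ≥ 70 %, both inclusive — "remove below 35/70" keeps exact
boundary values.  Coverage defaults to the single best HSP's span
(`best_hsp`); a `merged_hsps` basis (length of the union of the best
query's HSP intervals) is offered because the computation basis is
genuinely underdetermined, and merged coverage is never smaller.

Pairwise identity is a global affine-gap alignment (match +1, mismatch
−1, gap open −5, gap extend −1, end gaps penalized), with identity =
identical columns / shorter sequence length — the convention of
CD-HIT-style merging.  Because co-optimal alignments can disagree on the
identical-column count, the aligner maximizes the pair (score, matches)
lexicographically in one Gotoh pass, which is exact (edge increments are
history-independent) and makes the reported identity deterministic.
Greedy clustering visits sequences longest-first (ties lexicographic) and
joins the first representative at ≥ threshold, the classic greedy
incremental scheme.  The aligner is pure Python, O(nm) per pair; it is
comfortable at the peptide lengths and set sizes used here (≲100 aa,
dozens of sequences), and the scoring is configurable.

## Synthetic data: what it emulates, what it does not

The generator stands in for the proprietary occurrence databases.  It
emulates the *structural* features the pipeline must survive — cores
hidden under hydroxyls, carbonyls, desaturations, missing methyls, acyl
esters and glycosides; multi-source occurrence with unequal coverage;
boundary-valued homology hits — with exact ground truth by construction.
Default decoration probabilities (hydroxylation 0.8, desaturation 0.5,
carbonyl 0.3, esterification 0.3, glycosylation 0.1, demethylation 0.05)
reflect that real diterpenoids are overwhelmingly oxygenated, frequently
desaturated and only occasionally nor-skeletons; they are conditions, not
tuning knobs.  Decorations are applied to the graph under explicit
valence accounting (C ≤ 4, O ≤ 2), so every structure is valid with no
rejection sampling.  The glycoside is a fixed C6 pyranose and acyl chains
are capped at C6 by default, so no decoration fragment can out-compete a
C19–C20 core; when demethylation shrinks the core, the ground-truth label
records the *resulting* nor-skeleton.  Taxonomies are generated
clade-partition-first (every clade gets a genus round-robin), making
clade marginals exact.  One numpy Generator seeded from the config drives
everything, so reruns are byte-identical.

What it does **not** emulate: real reaction chemistry, realistic
decoration co-occurrence statistics, skewed genus sampling (the *Salvia*
problem), misannotated terpene classes, or name synonymy across sources.
Passing tests therefore demonstrate algorithmic correctness on inputs
with the right structure, not curation quality on real databases.

## Problem sizes and numerical choices

The acceptance measurements use: 200 decorated compounds (seeded) for
skeleton recovery; 1,000 random valence-legal molecules ≤ 30 atoms for
selection-oracle agreement and carbon conservation; 500 relabelings plus
200 random pairs ≤ 16 carbons for canonical-ID checks; 60 decorated
labdane/clerodane fixtures × 5 queries for pattern-oracle agreement; 120
subjects, a 6×6 threshold grid and 20 peptides in 5 families for the
filter/cluster checks.  These sizes give each check enough variety to
exercise every branch while keeping the whole script in seconds on one
CPU.  All equality checks are exact (graph isomorphism, set equality,
boolean agreement); the only floating-point comparisons are identity /
coverage thresholds, evaluated with `>=` as the inclusive rule demands.

## Known limitations

* The curated chemotaxonomic tables (skeleton distribution over genera
  and clades, enzyme reference set) come from proprietary sources and are
  not shipped; the code paths that consume them are exercised on
  synthetic tables, and the one test that reproduces the published counts
  fails until a user supplies the tables under `data/curated/`.
* The reference library covers six classic diterpene skeletons; pattern
  queries are limited to skeletons present in the library because they
  need a numbering map.
* Fuzzy name resolution is a plain edit-distance heuristic; it flags,
  but cannot adjudicate, genuine taxonomic synonymy.
* The pairwise aligner is quadratic Python; merging thousands of
  full-length proteins would call for a compiled aligner behind the same
  interface.
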