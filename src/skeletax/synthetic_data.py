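"""Seeded generators for labeled synthetic inputs.

The occurrence databases behind skeleton-based chemotaxonomy (structure
collections, name-only literature compilations) are proprietary, so every
analysis stage here is exercised on synthetic data with known ground truth:

* compound libraries built by decorating reference diterpene skeletons with
  the modification chemistry the real databases are full of — hydroxylation,
  carbonyls, desaturation, demethylation, esterification with short acyl
  chains, glycosylation — each compound labeled with the skeleton it was
  built from;
* a genus/clade taxonomy generated clade-partition-first, so clade marginals
  are exact by construction, plus randomized occurrence tables over it;
* randomized homology-hit tables and peptide families with ground-truth
  filter and cluster outcomes.

All randomness flows from one integer seed through one numpy Generator, so
a config reproduces every output byte for byte.  Decorations are applied to
the molecular graph under explicit valence accounting (C<=4 bonds, O<=2),
so every emitted structure is chemically valid by construction — no
rejection sampling.  The glycoside unit is a fixed C6 pyranose and acyl
chains are capped (default C6), so no decoration fragment can beat a C19+
core for the closest-to-20 selection; ground truth records the intended
core in the rare case demethylation shrinks it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_io import CompoundRecord, standardize, to_smiles
from .graph import Atom, Bond, MolecularGraph
from .skeleton import SkeletonLibrary, canonical_skeleton_id, default_library
from .taxonomy import CladeMap, TaxonRecord

DEFAULT_TEMPLATES = (
    "Sk1 kaurane", "Sk2 clerodane", "Sk3 abietane",
    "Sk4 labdane", "Sk6 pimarane", "Sk14 atisane",
)

DEFAULT_CLADE_NAMES = (
    "Ajugoideae", "Callicarpoideae", "Cymarioideae", "Lamioideae",
    "Nepetoideae", "Peronematoideae", "Premnoideae", "Prostantheroideae",
    "Scutellarioideae", "Symphorematoideae", "Tectonoideae", "Viticoideae",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic inputs.

    Decoration probabilities are per-compound chances that one decoration
    of that kind is applied; they emulate the modification spectrum of
    real diterpenoid collections (most compounds oxygenated, desaturation
    common, nor-diterpenes rare).
    """

    seed: int = 0
    n_compounds: int = 200
    templates: Sequence[str] = DEFAULT_TEMPLATES
    p_hydroxylation: float = 0.8
    p_carbonyl: float = 0.3
    p_desaturation: float = 0.5
    p_demethylation: float = 0.05
    p_esterification: float = 0.3
    p_glycosylation: float = 0.1
    max_acyl_carbons: int = 6
    # taxonomy shape
    n_genera: int = 30
    n_clades: int = 12
    species_per_genus: int = 4
    occurrence_density: float = 0.05
    source_densities: dict = field(
        default_factory=lambda: {
            "DNP-like": 1.0, "SISTEMAT-like": 0.5, "NAPRALERT-like": 0.4
        }
    )
    # hit-table shape
    n_subjects: int = 60
    n_queries: int = 8
    query_length: int = 500

    def validate(self) -> None:
        probs = [
            self.p_hydroxylation, self.p_carbonyl, self.p_desaturation,
            self.p_demethylation, self.p_esterification, self.p_glycosylation,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("decoration probabilities must be in [0,1]")
        if not (1 <= self.n_clades <= 12):
            raise ValueError("n_clades must be in 1..12")
        if self.max_acyl_carbons < 1:
            raise ValueError("max_acyl_carbons must be >= 1")


# ---------------------------------------------------------------------------
# Mutable graph scaffolding for decoration
# ---------------------------------------------------------------------------

_VALENCE = {"C": 4, "O": 2}


class _Builder:
    """Mutable molecular graph with valence accounting."""

    def __init__(self, graph: MolecularGraph):
        self.elements: dict[int, str] = {
            a.index: a.element for a in graph.atoms
        }
        self.orders: dict[tuple[int, int], int] = {
            b.key(): int(b.order) for b in graph.bonds
        }
        self._next = max(self.elements, default=-1) + 1

    def used_valence(self, i: int) -> int:
        return sum(o for k, o in self.orders.items() if i in k)

    def free_valence(self, i: int) -> int:
        return _VALENCE[self.elements[i]] - self.used_valence(i)

    def add_atom(self, element: str) -> int:
        idx = self._next
        self._next += 1
        self.elements[idx] = element
        return idx

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        key = (i, j) if i < j else (j, i)
        assert key not in self.orders
        self.orders[key] = order

    def remove_atom(self, i: int) -> None:
        del self.elements[i]
        self.orders = {k: o for k, o in self.orders.items() if i not in k}

    def degree(self, i: int) -> int:
        return sum(1 for k in self.orders if i in k)

    def to_graph(self) -> MolecularGraph:
        remap = {old: new for new, old in enumerate(sorted(self.elements))}
        atoms = [
            Atom(remap[i], el) for i, el in sorted(self.elements.items())
        ]
        bonds = [
            Bond(remap[i], remap[j], o)
            for (i, j), o in sorted(self.orders.items())
        ]
        g = MolecularGraph(atoms, bonds)
        g.validate()
        return g


def _core_carbons(b: _Builder, core: set[int]) -> list[int]:
    return sorted(i for i in core if i in b.elements)


def _attach_hydroxyl(b: _Builder, rng, core: set[int]) -> bool:
    sites = [i for i in _core_carbons(b, core) if b.free_valence(i) >= 1]
    if not sites:
        return False
    site = int(rng.choice(sites))
    o = b.add_atom("O")
    b.add_bond(site, o, 1)
    return True


def _attach_carbonyl(b: _Builder, rng, core: set[int]) -> bool:
    sites = [i for i in _core_carbons(b, core) if b.free_valence(i) >= 2]
    if not sites:
        return False
    site = int(rng.choice(sites))
    o = b.add_atom("O")
    b.add_bond(site, o, 2)
    return True


def _desaturate(b: _Builder, rng, core: set[int]) -> bool:
    candidates = [
        (i, j)
        for (i, j), o in sorted(b.orders.items())
        if o == 1 and i in core and j in core
        and b.elements.get(i) == "C" and b.elements.get(j) == "C"
        and b.free_valence(i) >= 1 and b.free_valence(j) >= 1
    ]
    if not candidates:
        return False
    i, j = candidates[int(rng.integers(len(candidates)))]
    b.orders[(i, j)] = 2
    return True


def _demethylate(b: _Builder, rng, core: set[int]) -> Optional[int]:
    methyls = [
        i for i in _core_carbons(b, core)
        if b.degree(i) == 1 and b.used_valence(i) == 1
    ]
    if not methyls:
        return None
    target = int(rng.choice(methyls))
    b.remove_atom(target)
    return target


def _attach_ester(b: _Builder, rng, core: set[int], max_acyl: int) -> bool:
    """O-acylate a core carbon: site-O-C(=O)-(C)n-1 with n acyl carbons."""
    sites = [i for i in _core_carbons(b, core) if b.free_valence(i) >= 1]
    if not sites:
        return False
    site = int(rng.choice(sites))
    n_acyl = int(rng.integers(1, max_acyl + 1))
    o_ester = b.add_atom("O")
    b.add_bond(site, o_ester, 1)
    c_carbonyl = b.add_atom("C")
    b.add_bond(o_ester, c_carbonyl, 1)
    o_carbonyl = b.add_atom("O")
    b.add_bond(c_carbonyl, o_carbonyl, 2)
    prev = c_carbonyl
    for _ in range(n_acyl - 1):
        c = b.add_atom("C")
        b.add_bond(prev, c, 1)
        prev = c
    return True


def _attach_glycoside(b: _Builder, rng, core: set[int]) -> bool:
    """O-glycosylate with a fixed C6 pyranose (glucose-like constitution)."""
    sites = [i for i in _core_carbons(b, core) if b.free_valence(i) >= 1]
    if not sites:
        return False
    site = int(rng.choice(sites))
    o_gly = b.add_atom("O")
    b.add_bond(site, o_gly, 1)
    ring_c = [b.add_atom("C") for _ in range(5)]  # C1'..C5'
    o_ring = b.add_atom("O")
    b.add_bond(o_gly, ring_c[0], 1)
    for a, c in zip(ring_c, ring_c[1:]):
        b.add_bond(a, c, 1)
    b.add_bond(ring_c[4], o_ring, 1)
    b.add_bond(o_ring, ring_c[0], 1)
    c6 = b.add_atom("C")
    b.add_bond(ring_c[4], c6, 1)
    for idx in (ring_c[1], ring_c[2], ring_c[3], c6):
        oh = b.add_atom("O")
        b.add_bond(idx, oh, 1)
    return True


# ---------------------------------------------------------------------------
# Compound generation
# ---------------------------------------------------------------------------

def generate_compounds(
    config: GeneratorConfig,
    library: Optional[SkeletonLibrary] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Generate decorated compounds with ground-truth skeleton labels.

    Returns the records (graphs standardized, structure_text = canonical
    SMILES) and a ground-truth table with one row per compound:
    compound_id, template, expected_skeleton_id (canonical ID of the core
    actually present, accounting for demethylation), core_carbons, and the
    decorations applied.
    """
    config.validate()
    lib = library or default_library()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    for t in config.templates:
        lib.get(t)  # KeyError on unknown template
    records: list[CompoundRecord] = []
    truth_rows = []
    for i in range(config.n_compounds):
        cid = f"SYN{i + 1:05d}"
        template = str(rng.choice(list(config.templates)))
        sk, _ = lib.get(template)
        b = _Builder(sk.graph)
        core = {a.index for a in sk.graph.atoms}
        decorations = []
        # structural edits first (they change the core), then the rest
        if rng.random() < config.p_demethylation:
            removed = _demethylate(b, rng, core)
            if removed is not None:
                core.discard(removed)
                decorations.append("demethylation")
        if rng.random() < config.p_desaturation and _desaturate(b, rng, core):
            decorations.append("desaturation")
        if rng.random() < config.p_hydroxylation and _attach_hydroxyl(
            b, rng, core
        ):
            decorations.append("hydroxylation")
        if rng.random() < config.p_carbonyl and _attach_carbonyl(b, rng, core):
            decorations.append("carbonyl")
        if rng.random() < config.p_esterification and _attach_ester(
            b, rng, core, config.max_acyl_carbons
        ):
            decorations.append("esterification")
        if rng.random() < config.p_glycosylation and _attach_glycoside(
            b, rng, core
        ):
            decorations.append("glycosylation")
        graph = standardize(b.to_graph())
        smiles = to_smiles(graph)
        # expected core from construction: the surviving template atoms with
        # the template's own bonds, all orders 1 — independent of the
        # extraction pipeline
        remap = {old: new for new, old in enumerate(sorted(core))}
        core_graph = MolecularGraph(
            atoms=[Atom(n, "C") for n in range(len(core))],
            bonds=[
                Bond(remap[b.i], remap[b.j], 1)
                for b in sk.graph.bonds
                if b.i in remap and b.j in remap
            ],
        )
        expected_id = canonical_skeleton_id(core_graph)
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=f"{template} derivative {i + 1}",
                structure_text=smiles,
                graph=graph,
                source_db="synthetic",
            )
        )
        truth_rows.append(
            {
                "compound_id": cid,
                "template": template,
                "expected_skeleton_id": expected_id,
                "core_carbons": len(core),
                "decorations": ";".join(decorations),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "compound_id", "template", "expected_skeleton_id",
            "core_carbons", "decorations",
        ],
    )
    return records, truth


# ---------------------------------------------------------------------------
# Taxonomy and occurrence generation
# ---------------------------------------------------------------------------

def generate_taxonomy(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[TaxonRecord], CladeMap]:
    """Genus->clade partition first, species second.

    Every clade receives at least one genus (round-robin), so clade
    marginals are exact by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    clades = list(DEFAULT_CLADE_NAMES[: config.n_clades])
    records: list[TaxonRecord] = []
    clade_rows = []
    next_id = 1000
    for g in range(config.n_genera):
        genus = f"Genus{g + 1:03d}"
        clade = clades[g % len(clades)]
        clade_rows.append((genus, clade))
        genus_id = next_id
        next_id += 1
        records.append(TaxonRecord(genus_id, genus, "genus", None))
        for s in range(config.species_per_genus):
            records.append(
                TaxonRecord(
                    next_id, f"{genus} species{s + 1}", "species", genus_id
                )
            )
            next_id += 1
    return records, CladeMap(clade_rows)


def generate_occurrence(
    config: GeneratorConfig,
    compounds: Sequence[CompoundRecord],
    taxonomy: Sequence[TaxonRecord],
    clade_map: CladeMap,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample compound x species occurrence rows and exact true marginals.

    Each (compound, species) pair is reported with probability
    ``occurrence_density``; every compound is forced into at least one
    species so downstream statistics are total.  Each reported pair then
    appears in each source with that source's density (the first source is
    always present).  True per-compound marginals (n_genera, n_clades) are
    computed exhaustively from the sampled rows themselves.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    species = [t for t in taxonomy if t.rank == "species"]
    genus_name = {
        t.taxon_id: t.canonical_name.split(" ")[0].lower()
        for t in taxonomy
    }
    sources = list(config.source_densities)
    rows = []
    for comp in compounds:
        present = [
            sp for sp in species if rng.random() < config.occurrence_density
        ]
        if not present:
            present = [species[int(rng.integers(len(species)))]]
        for sp in present:
            genus = genus_name[sp.parent_genus_id]
            for k, source in enumerate(sources):
                density = config.source_densities[source]
                if k == 0 or rng.random() < density:
                    rows.append(
                        {
                            "compound_id": comp.compound_id,
                            "taxon_id": sp.taxon_id,
                            "genus": genus,
                            "clade": clade_map.assign(genus),
                            "source_db": source,
                        }
                    )
    occ = pd.DataFrame(
        rows,
        columns=["compound_id", "taxon_id", "genus", "clade", "source_db"],
    )
    marg_rows = []
    for cid, grp in occ.groupby("compound_id"):
        marg_rows.append(
            {
                "compound_id": cid,
                "n_genera": grp["genus"].nunique(),
                "n_clades": grp.loc[
                    grp["clade"] != "unassigned", "clade"
                ].nunique(),
            }
        )
    marginals = pd.DataFrame(
        marg_rows, columns=["compound_id", "n_genera", "n_clades"]
    )
    return occ, marginals


# ---------------------------------------------------------------------------
# Homology hits and peptides
# ---------------------------------------------------------------------------

def generate_hits(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, dict[str, int], set[str]]:
    """Random 12-column hit table + ground-truth retained subject set.

    Identities are drawn uniformly over [20, 100] (rounded to 0.1, so
    boundary values like exactly 35.0 occur), coverage fractions uniformly
    over [0.4, 1.0].  Ground truth is computed by exhaustive application
    of the filter rule (best hit by bitscore; identity >= 35 and coverage
    >= 70, inclusive) under the best_hsp coverage basis.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    qlen = config.query_length
    queries = [f"Q{q + 1:03d}" for q in range(config.n_queries)]
    query_lengths = {q: qlen for q in queries}
    rows = []
    for s in range(config.n_subjects):
        subject = f"S{s + 1:04d}"
        n_hits = int(rng.integers(1, 4))
        hit_queries = rng.choice(queries, size=n_hits, replace=False)
        for q in hit_queries:
            identity = round(float(rng.uniform(20.0, 100.0)), 1)
            if rng.random() < 0.05:
                identity = float(rng.choice([35.0, 70.0]))  # boundary cases
            cov_frac = float(rng.uniform(0.4, 1.0))
            if rng.random() < 0.05:
                cov_frac = 0.7
            span = max(1, int(round(cov_frac * qlen)))
            q_start = int(rng.integers(1, qlen - span + 2))
            q_end = q_start + span - 1
            bitscore = round(float(rng.uniform(50.0, 900.0)), 1)
            rows.append(
                {
                    "query_id": str(q),
                    "subject_id": subject,
                    "percent_identity": identity,
                    "alignment_length": span,
                    "mismatches": int(round(span * (1 - identity / 100.0))),
                    "gap_opens": 0,
                    "q_start": q_start,
                    "q_end": q_end,
                    "s_start": 1,
                    "s_end": span,
                    "evalue": 1e-30,
                    "bitscore": bitscore,
                }
            )
    table = pd.DataFrame(rows)
    # exhaustive ground truth, independent bookkeeping
    retained = set()
    for subject, grp in table.groupby("subject_id"):
        grp = grp.sort_values(
            ["bitscore", "percent_identity", "query_id"],
            ascending=[False, False, True],
        )
        best = grp.iloc[0]
        coverage = 100.0 * (best.q_end - best.q_start + 1) / qlen
        if best.percent_identity >= 35.0 and coverage >= 70.0:
            retained.add(str(subject))
    return table, query_lengths, retained


# ---------------------------------------------------------------------------
# Random graph generators (inputs for oracle-style checks)
# ---------------------------------------------------------------------------

def random_molecular_graph(
    rng: np.random.Generator, max_atoms: int = 30
) -> MolecularGraph:
    """Random valence-respecting multi-element graph (1-3 components).

    Exercises saturate-and-fragment and fragment selection over arbitrary
    connectivity; not guaranteed to be a sensible molecule, only a legal
    graph (C<=4, O<=2, N<=3 total bond order)."""
    valence = {"C": 4, "O": 2, "N": 3}
    n = int(rng.integers(2, max_atoms + 1))
    elements = [
        str(rng.choice(["C", "C", "C", "C", "O", "N"])) for _ in range(n)
    ]
    atoms = [Atom(i, el) for i, el in enumerate(elements)]
    used = [0] * n
    bonds: list[Bond] = []
    present: set[tuple[int, int]] = set()
    order = list(rng.permutation(n))
    n_comp = int(rng.integers(1, 4))
    comp_of = {idx: k % n_comp for k, idx in enumerate(order)}
    members_of: dict[int, list[int]] = {}
    for idx in order:
        members = members_of.setdefault(comp_of[idx], [])
        anchors = [a for a in members if used[a] < valence[elements[a]]]
        if members and anchors and used[idx] < valence[elements[idx]]:
            a = int(rng.choice(anchors))
            bonds.append(Bond(*sorted((a, idx)), 1))
            present.add(tuple(sorted((a, idx))))
            used[a] += 1
            used[idx] += 1
        members.append(idx)
    for _ in range(int(rng.integers(0, n))):
        i, j = int(rng.integers(n)), int(rng.integers(n))
        key = tuple(sorted((i, j)))
        if i == j or key in present or comp_of[i] != comp_of[j]:
            continue
        order_choice = 2 if rng.random() < 0.2 else 1
        if (
            used[i] + order_choice <= valence[elements[i]]
            and used[j] + order_choice <= valence[elements[j]]
        ):
            bonds.append(Bond(key[0], key[1], order_choice))
            present.add(key)
            used[i] += order_choice
            used[j] += order_choice
    g = MolecularGraph(atoms, bonds)
    g.validate()
    return g


def random_carbon_fragment_graph(
    rng: np.random.Generator, n_carbons: int
) -> MolecularGraph:
    """Random connected all-carbon single-bond graph with degree <= 4."""
    atoms = [Atom(i, "C") for i in range(n_carbons)]
    used = [0] * n_carbons
    bonds: list[Bond] = []
    present: set[tuple[int, int]] = set()
    for idx in range(1, n_carbons):
        anchors = [a for a in range(idx) if used[a] < 4]
        a = int(rng.choice(anchors))
        bonds.append(Bond(a, idx, 1))
        present.add((a, idx))
        used[a] += 1
        used[idx] += 1
    for _ in range(int(rng.integers(0, max(1, n_carbons // 2)))):
        i, j = sorted(
            (int(rng.integers(n_carbons)), int(rng.integers(n_carbons)))
        )
        if i == j or (i, j) in present:
            continue
        if used[i] < 4 and used[j] < 4:
            bonds.append(Bond(i, j, 1))
            present.add((i, j))
            used[i] += 1
            used[j] += 1
    g = MolecularGraph(atoms, bonds)
    g.validate()
    return g


def permute_graph(
    graph: MolecularGraph, rng: np.random.Generator
) -> MolecularGraph:
    """Relabel atoms by a random permutation (an isomorphic copy)."""
    perm = list(rng.permutation(graph.n_atoms))
    atoms = sorted(
        (Atom(perm[a.index], a.element, a.formal_charge)
         for a in graph.atoms),
        key=lambda a: a.index,
    )
    bonds = [
        Bond(*sorted((perm[b.i], perm[b.j])), b.order) for b in graph.bonds
    ]
    g = MolecularGraph(atoms, bonds)
    g.validate()
    return g


_AA = "ACDEFGHIKLMNPQRSTVWY"


def generate_peptides(
    n_families: int = 5,
    members_per_family: int = 4,
    length: int = 80,
    within_family_mutations: int = 2,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Random peptide families for clustering tests.

    Members of a family differ from the founder by a few substitutions
    (>= 95% identity for the defaults); founders are independent random
    sequences (far below any merge threshold).  Returns (sequences,
    family-of-sequence) maps.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    family: dict[str, str] = {}
    for f in range(n_families):
        founder = "".join(rng.choice(list(_AA), size=length))
        fam = f"F{f + 1:02d}"
        for m in range(members_per_family):
            sid = f"{fam}_M{m + 1:02d}"
            if m == 0:
                seq = founder
            else:
                s = list(founder)
                sites = rng.choice(
                    length, size=within_family_mutations, replace=False
                )
                for pos in sites:
                    choices = [a for a in _AA if a != s[pos]]
                    s[int(pos)] = str(rng.choice(choices))
                seq = "".join(s)
            seqs[sid] = seq
            family[sid] = fam
    return seqs, family


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(sequences):
            fh.write(f">{sid}\n{sequences[sid]}\n")
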