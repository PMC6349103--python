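"""Carbon-skeleton extraction, canonical identity and the reference library.

The skeleton of a natural product is its core alkane: the carbon graph left
after discarding heteroatoms, bond orders, substituent fragments and
stereochemistry.  For diterpenoids the extraction rule is

1. convert every bond to a single bond,
2. break every bond that involves at least one non-carbon atom,
3. keep the fragment whose carbon count is closest to 20.

Skeleton identity is graph isomorphism of the resulting unlabeled carbon
graph; we realize it as the canonical SMILES of the saturated hydrocarbon,
which two fragments share iff they are isomorphic.

The shipped reference library covers the classic diterpene skeletons
(kaurane, clerodane, abietane, labdane, pimarane, atisane) as edge lists
over the conventional diterpene position numbering 1..20, so position *p*
is atom index *p - 1* in the library graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
from rdkit import Chem

from .chem_io import CompoundRecord
from .graph import MolecularGraph, carbon_graph, mol_from_graph


class NoCarbonSkeletonError(ValueError):
    pass


@dataclass
class Skeleton:
    """A connected, all-carbon, all-single-bond core graph."""

    skeleton_id: str
    carbon_count: int
    graph: MolecularGraph
    ring_count: int
    reference_name: Optional[str] = None
    #: indices of the skeleton atoms in the originating compound graph,
    #: parallel to graph atom order; needed for positional pattern queries
    atom_indices: tuple[int, ...] = ()


@dataclass
class SkeletonAssignment:
    compound_id: str
    skeleton: Skeleton
    fragment_carbon_counts: list[int]
    ambiguous: bool = False
    override_applied: bool = False


@dataclass
class SkeletonLibrary:
    """Named reference skeletons with their position-numbering maps.

    ``position_numbering`` maps a library-graph atom index to the diterpene
    position number (1..20 for C20 skeletons), bijectively.
    """

    entries: list[tuple[str, Skeleton, dict[int, int]]] = field(
        default_factory=list
    )

    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def get(self, name: str) -> tuple[Skeleton, dict[int, int]]:
        for n, sk, numbering in self.entries:
            if n == name:
                return sk, numbering
        raise KeyError(name)

    def match(self, skeleton_id: str) -> Optional[str]:
        """Reference name whose skeleton is isomorphic to ``skeleton_id``."""
        for name, sk, _ in self.entries:
            if sk.skeleton_id == skeleton_id:
                return name
        return None


# ---------------------------------------------------------------------------
# Core algorithm
# ---------------------------------------------------------------------------

def saturate_and_fragment(graph: MolecularGraph) -> list[Skeleton]:
    """Apply the saturate-and-fragment rule to a standardized graph.

    All bond orders are set to 1, every bond touching a non-carbon atom is
    broken, non-carbon atoms are discarded, and each resulting connected
    carbon component is returned as an (unmatched) :class:`Skeleton`.  The
    fragments partition the carbon atoms of the input exactly.
    """
    carbon_idx = [a.index for a in graph.atoms if a.element == "C"]
    if not carbon_idx:
        raise NoCarbonSkeletonError("no carbon skeleton: molecule has no C")
    g = nx.Graph()
    g.add_nodes_from(carbon_idx)
    for b in graph.bonds:
        if graph.element(b.i) == "C" and graph.element(b.j) == "C":
            g.add_edge(b.i, b.j)  # order forced to 1 by construction
    fragments = []
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        sub = graph.subgraph(nodes)
        frag = MolecularGraph(
            atoms=[type(a)(a.index, "C", 0) for a in sub.atoms],
            bonds=[type(b)(b.i, b.j, 1) for b in sub.bonds],
        )
        fragments.append(
            Skeleton(
                skeleton_id=canonical_skeleton_id(frag),
                carbon_count=len(nodes),
                graph=frag,
                ring_count=cycle_rank(frag),
                atom_indices=tuple(nodes),
            )
        )
    assert sum(f.carbon_count for f in fragments) == len(carbon_idx)
    return fragments


def cycle_rank(graph: MolecularGraph) -> int:
    """Number of independent rings (circuit rank) of a connected graph."""
    n_comp = len(graph.connected_components())
    return len(graph.bonds) - graph.n_atoms + n_comp


def canonical_skeleton_id(fragment: MolecularGraph) -> str:
    """Isomorphism-invariant identifier of an all-carbon single-bond graph.

    Realized as the canonical SMILES of the corresponding saturated
    hydrocarbon: two fragments receive the same ID iff their unlabeled
    graphs are isomorphic.
    """
    if len(fragment.connected_components()) != 1:
        raise ValueError("skeleton fragment must be connected")
    for a in fragment.atoms:
        if a.element != "C":
            raise ValueError("skeleton fragment must be all-carbon")
    for b in fragment.bonds:
        if b.order != 1:
            raise ValueError("skeleton fragment must be all-single-bond")
    return Chem.MolToSmiles(mol_from_graph(fragment))


def select_skeleton_fragment(
    fragments: Sequence[Skeleton],
    target: int = 20,
    margin: int = 0,
    override_id: Optional[str] = None,
) -> tuple[Skeleton, bool]:
    """Pick the fragment whose carbon count is closest to ``target``.

    Ties in |carbon_count - target| are broken deterministically: more
    rings first, then more carbons, then lexicographically smaller
    canonical ID.  The returned flag is true when the winner and runner-up
    distances differ by at most ``margin`` (i.e. the tie rule, not the
    distance, decided) — those assignments are the machine-assisted-review
    channel mirroring the curation step where wrong automatic choices were
    corrected by hand.  ``override_id`` short-circuits the automatic
    choice by canonical fragment ID.
    """
    if not fragments:
        raise ValueError("no fragments to select from")
    if override_id is not None:
        for f in fragments:
            if f.skeleton_id == override_id:
                return f, False
        raise KeyError(f"override skeleton id {override_id!r} not among fragments")

    def sort_key(f: Skeleton):
        return (
            abs(f.carbon_count - target),
            -f.ring_count,
            -f.carbon_count,
            f.skeleton_id,
        )

    ranked = sorted(fragments, key=sort_key)
    best = ranked[0]
    ambiguous = False
    if len(ranked) > 1:
        d0 = abs(best.carbon_count - target)
        d1 = abs(ranked[1].carbon_count - target)
        ambiguous = (d1 - d0) <= margin
    return best, ambiguous


@dataclass
class ExtractionConfig:
    target: int = 20
    margin: int = 0
    #: compound_id -> canonical fragment ID chosen by manual review
    overrides: Mapping[str, str] = field(default_factory=dict)


def extract_skeleton(
    compound: CompoundRecord,
    library: Optional[SkeletonLibrary] = None,
    config: Optional[ExtractionConfig] = None,
) -> SkeletonAssignment:
    """Full skeleton extraction for one compound.

    Composes saturate-and-fragment with closest-to-target selection and
    library matching.  Idempotent on pure skeletons: feeding a skeleton
    back in returns the identical skeleton_id.
    """
    if compound.graph is None:
        raise ValueError(f"compound {compound.compound_id} has no graph")
    cfg = config or ExtractionConfig()
    fragments = saturate_and_fragment(compound.graph)
    override_id = cfg.overrides.get(compound.compound_id)
    chosen, ambiguous = select_skeleton_fragment(
        fragments, target=cfg.target, margin=cfg.margin, override_id=override_id
    )
    if library is not None:
        chosen.reference_name = library.match(chosen.skeleton_id)
    counts = sorted(f.carbon_count for f in fragments)
    return SkeletonAssignment(
        compound_id=compound.compound_id,
        skeleton=chosen,
        fragment_carbon_counts=counts,
        ambiguous=ambiguous,
        override_applied=override_id is not None,
    )


def dedup_skeletons(assignments: Iterable[SkeletonAssignment]) -> pd.DataFrame:
    """One row per distinct skeleton with its compound count.

    Columns: skeleton_id, carbon_count, reference_name, n_compounds;
    n_compounds sums to the number of assignments.
    """
    rows: dict[str, dict] = {}
    for a in assignments:
        sk = a.skeleton
        row = rows.setdefault(
            sk.skeleton_id,
            {
                "skeleton_id": sk.skeleton_id,
                "carbon_count": sk.carbon_count,
                "reference_name": sk.reference_name,
                "n_compounds": 0,
            },
        )
        row["n_compounds"] += 1
        if row["reference_name"] is None and sk.reference_name is not None:
            row["reference_name"] = sk.reference_name
    df = pd.DataFrame(
        list(rows.values()),
        columns=["skeleton_id", "carbon_count", "reference_name", "n_compounds"],
    )
    return df.sort_values(
        ["n_compounds", "skeleton_id"], ascending=[False, True]
    ).reset_index(drop=True)


def assignments_table(assignments: Iterable[SkeletonAssignment]) -> pd.DataFrame:
    """Flat per-compound CSV-ready view of assignments."""
    rows = [
        {
            "compound_id": a.compound_id,
            "skeleton_id": a.skeleton.skeleton_id,
            "carbon_count": a.skeleton.carbon_count,
            "reference_name": a.skeleton.reference_name,
            "ambiguous": a.ambiguous,
            "override_applied": a.override_applied,
            "fragment_carbon_counts": ";".join(
                str(c) for c in a.fragment_carbon_counts
            ),
        }
        for a in assignments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "skeleton_id",
            "carbon_count",
            "reference_name",
            "ambiguous",
            "override_applied",
            "fragment_carbon_counts",
        ],
    )


# ---------------------------------------------------------------------------
# Reference library
# ---------------------------------------------------------------------------
# Edge lists over conventional diterpene position numbers.  All six classic
# skeletons share the decalin core (rings A: 1-2-3-4-5-10, B: 5-6-7-8-9-10)
# and gem positions 18/19/20; they differ in the attachment of the C11-C16
# side chain / C and D rings and in methyl placement.

_DECALIN = [
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 10), (10, 1),
    (5, 6), (6, 7), (7, 8), (8, 9), (9, 10),
]

REFERENCE_SKELETON_EDGES: dict[str, list[tuple[int, int]]] = {
    # tetracyclic; C ring 8-14-13-12-11-9, D ring bridge 8-15-16-13, C17 on 16
    "Sk1 kaurane": _DECALIN + [
        (9, 11), (11, 12), (12, 13), (13, 14), (14, 8),
        (8, 15), (15, 16), (16, 13),
        (16, 17), (4, 18), (4, 19), (10, 20),
    ],
    # decalin with methyls rearranged to 4, 5, 8 and quaternary C9 bearing
    # both the C20 methyl and the C11 side chain
    "Sk2 clerodane": _DECALIN + [
        (9, 11), (11, 12), (12, 13), (13, 16), (13, 14), (14, 15),
        (4, 18), (5, 19), (8, 17), (9, 20),
    ],
    # tricyclic; C ring 8-14-13-12-11-9, isopropyl (15,16,17) on C13
    "Sk3 abietane": _DECALIN + [
        (9, 11), (11, 12), (12, 13), (13, 14), (14, 8),
        (13, 15), (15, 16), (15, 17),
        (4, 18), (4, 19), (10, 20),
    ],
    # bicyclic; gem-dimethyl C4, methyls at 8 and 10, side chain on C9
    "Sk4 labdane": _DECALIN + [
        (9, 11), (11, 12), (12, 13), (13, 16), (13, 14), (14, 15),
        (4, 18), (4, 19), (8, 17), (10, 20),
    ],
    # tricyclic; methyl C17 and ethyl C15-C16 both on quaternary C13
    "Sk6 pimarane": _DECALIN + [
        (9, 11), (11, 12), (12, 13), (13, 14), (14, 8),
        (13, 17), (13, 15), (15, 16),
        (4, 18), (4, 19), (10, 20),
    ],
    # tetracyclic; bicyclo[2.2.2]octane: C ring 8-14-13-12-11-9 plus
    # 8-15-16-12 bridge, C17 on 16
    "Sk14 atisane": _DECALIN + [
        (9, 11), (11, 12), (12, 13), (13, 14), (14, 8),
        (8, 15), (15, 16), (16, 12),
        (16, 17), (4, 18), (4, 19), (10, 20),
    ],
}


def default_library() -> SkeletonLibrary:
    """The shipped diterpene reference library (Sk1..Sk14 subset)."""
    lib = SkeletonLibrary()
    for name, edges in REFERENCE_SKELETON_EDGES.items():
        graph = carbon_graph(edges)
        sk = Skeleton(
            skeleton_id=canonical_skeleton_id(graph),
            carbon_count=graph.n_atoms,
            graph=graph,
            ring_count=cycle_rank(graph),
            reference_name=name,
        )
        numbering = {i: i + 1 for i in range(graph.n_atoms)}
        lib.entries.append((name, sk, numbering))
    return lib
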