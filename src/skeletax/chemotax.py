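"""Occurrence merging, distribution statistics and positional pattern counts.

Once compounds carry skeleton assignments and taxa are resolved to genera
and clades, the chemotaxonomic questions become counting exercises over an
occurrence table: in how many genera and how many of the 12 primary clades
has each skeleton been reported; how many compounds share each skeleton;
how do the source databases compare per genus; and how many compounds carry
a given positional structural pattern (e.g. a double bond between skeleton
positions 7 and 8 of the labdane core, or a 4(18) epoxide bridge on the
clerodane core).

Pattern queries follow the solid/dashed convention of chemotaxonomic
distribution figures: a *solid* constraint means only compounds with
exactly that bond type at that position count; *dashed* positions admit any
bond or substituent.  A compound matches when at least one isomorphism of
its skeleton onto the scoped reference skeleton satisfies every solid
constraint in the original (pre-saturation) structure — existential
semantics over automorphisms, so a compound never counts twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
import yaml

from .chem_io import CompoundRecord
from .graph import MolecularGraph
from .skeleton import SkeletonAssignment, SkeletonLibrary
from .taxonomy import CladeMap, TaxonRecord

log = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ["compound_id", "taxon_id", "genus", "clade", "source_db"]

#: sources whose records carry structures (name-only sources take part in
#: per-genus structure counts but not in skeleton statistics)
STRUCTURE_SOURCES = ("DNP-like", "SISTEMAT-like", "synthetic")
N_PRIMARY_CLADES = 12


# ---------------------------------------------------------------------------
# Occurrence table
# ---------------------------------------------------------------------------

def merge_occurrences(
    per_source: Mapping[str, pd.DataFrame],
    reference: Sequence[TaxonRecord],
    clade_map: CladeMap,
) -> pd.DataFrame:
    """Union per-source (compound_id, taxon_id) tables into one occurrence
    table with genus/clade annotation and source tags.

    Rows whose taxon_id is absent from the reference taxonomy are excluded
    (their count is logged).  Duplicate (compound_id, taxon_id, source_db)
    rows collapse to one.
    """
    by_id = {r.taxon_id: r for r in reference}
    genus_name = {
        r.taxon_id: r.canonical_name.split(" ")[0].lower() for r in reference
    }
    rows = []
    n_unresolved = 0
    for source, df in per_source.items():
        for row in df.itertuples(index=False):
            tid = int(row.taxon_id)
            rec = by_id.get(tid)
            if rec is None:
                n_unresolved += 1
                continue
            if rec.rank == "species" and rec.parent_genus_id in genus_name:
                genus = genus_name[rec.parent_genus_id]
            else:
                genus = genus_name[tid]
            rows.append(
                {
                    "compound_id": str(row.compound_id),
                    "taxon_id": tid,
                    "genus": genus,
                    "clade": clade_map.assign(genus),
                    "source_db": source,
                }
            )
    if n_unresolved:
        log.warning("excluded %d occurrence rows with unresolved taxa",
                    n_unresolved)
    occ = pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)
    occ = occ.drop_duplicates(
        subset=["compound_id", "taxon_id", "source_db"]
    ).reset_index(drop=True)
    return occ


@dataclass
class DistributionSummary:
    """Per-skeleton and per-genus marginals of an occurrence table."""

    per_skeleton: pd.DataFrame  # skeleton_id, n_compounds, n_genera, n_clades
    per_genus: pd.DataFrame     # genus, n_compounds, n_skeletons, + per-source

    def observed_skeletons(self) -> set[str]:
        return set(self.per_skeleton["skeleton_id"])


def skeleton_distribution(
    occ: pd.DataFrame,
    assignments: Mapping[str, SkeletonAssignment],
    structure_sources: Sequence[str] = STRUCTURE_SOURCES,
) -> DistributionSummary:
    """Compute the distribution marginals of skeletons over genera/clades.

    Skeleton statistics use only structure-bearing sources; every compound
    in those rows must carry an assignment (missing ones are an error that
    names the offending compound_ids).  Per-genus rows additionally count
    name-only records as structures.
    """
    struct = occ[occ["source_db"].isin(structure_sources)]
    missing = sorted(set(struct["compound_id"]) - set(assignments))
    if missing:
        raise KeyError(
            "compounds without skeleton assignment: " + ", ".join(missing)
        )
    skel_of = {cid: a.skeleton.skeleton_id for cid, a in assignments.items()}

    sk_rows: dict[str, dict] = {}
    for cid, grp in struct.groupby("compound_id"):
        sid = skel_of[cid]
        row = sk_rows.setdefault(
            sid,
            {"skeleton_id": sid, "compounds": set(), "genera": set(),
             "clades": set()},
        )
        row["compounds"].add(cid)
        row["genera"].update(grp["genus"])
        row["clades"].update(c for c in grp["clade"] if c != "unassigned")
    per_skeleton = pd.DataFrame(
        [
            {
                "skeleton_id": r["skeleton_id"],
                "n_compounds": len(r["compounds"]),
                "n_genera": len(r["genera"]),
                "n_clades": len(r["clades"]),
            }
            for r in sk_rows.values()
        ],
        columns=["skeleton_id", "n_compounds", "n_genera", "n_clades"],
    ).sort_values("skeleton_id").reset_index(drop=True)

    genus_rows = []
    for genus, grp in occ.groupby("genus"):
        row = {
            "genus": genus,
            "n_compounds": grp["compound_id"].nunique(),
            "n_skeletons": len(
                {
                    skel_of[c]
                    for c in grp.loc[
                        grp["source_db"].isin(structure_sources), "compound_id"
                    ]
                }
            ),
        }
        for source in sorted(occ["source_db"].unique()):
            row[f"n_compounds[{source}]"] = grp.loc[
                grp["source_db"] == source, "compound_id"
            ].nunique()
        genus_rows.append(row)
    per_genus = pd.DataFrame(genus_rows).sort_values("genus").reset_index(
        drop=True
    ) if genus_rows else pd.DataFrame(
        columns=["genus", "n_compounds", "n_skeletons"]
    )
    return DistributionSummary(per_skeleton, per_genus)


def unknown_route_skeletons(
    distribution: DistributionSummary,
    known_enzyme_products: pd.DataFrame,
    library: SkeletonLibrary,
) -> set[str]:
    """Observed skeletons minus those reachable by known enzyme products.

    ``known_enzyme_products`` must carry a ``product_skeleton`` column of
    library reference names (e.g. "Sk4 labdane"); unknown reference names
    are an error.
    """
    known_ids = set()
    for name in known_enzyme_products["product_skeleton"].dropna().unique():
        sk, _ = library.get(str(name))  # KeyError on unknown reference
        known_ids.add(sk.skeleton_id)
    return distribution.observed_skeletons() - known_ids


def database_overlap(occ: pd.DataFrame) -> pd.DataFrame:
    """Per-genus pairwise source comparison.

    For every genus and ordered source pair (a < b): the number of distinct
    compounds per source and the intersection size, matching on
    compound_id (name-only sources use the name as their compound key).
    Requires at least two sources.
    """
    sources = sorted(occ["source_db"].unique())
    if len(sources) < 2:
        raise ValueError("database_overlap requires at least two sources")
    rows = []
    for genus, grp in occ.groupby("genus"):
        per_source = {
            s: set(grp.loc[grp["source_db"] == s, "compound_id"])
            for s in sources
        }
        for i, a in enumerate(sources):
            for b in sources[i + 1:]:
                rows.append(
                    {
                        "genus": genus,
                        "source_a": a,
                        "source_b": b,
                        "n_a": len(per_source[a]),
                        "n_b": len(per_source[b]),
                        "n_both": len(per_source[a] & per_source[b]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["genus", "source_a", "source_b", "n_a", "n_b", "n_both"]
    )


# ---------------------------------------------------------------------------
# Positional pattern queries
# ---------------------------------------------------------------------------

DOUBLE_BOND = "double_bond"
EPOXIDE_BRIDGE = "epoxide_bridge"
ANY = "any"


@dataclass(frozen=True)
class PatternConstraint:
    positions: tuple[int, ...]  # one or two skeleton position numbers
    kind: str                   # double_bond | epoxide_bridge | any
    solid: bool = True          # solid = exact requirement, dashed = wildcard


@dataclass
class PatternQuery:
    name: str
    skeleton_scope: str  # library reference name, e.g. "Sk4 labdane"
    constraints: list[PatternConstraint] = field(default_factory=list)

    def solid_constraints(self) -> list[PatternConstraint]:
        return [c for c in self.constraints if c.solid and c.kind != ANY]


def _fragment_nx(skeleton) -> nx.Graph:
    """Skeleton fragment as an nx graph over ORIGINAL compound atom indices."""
    g = nx.Graph()
    idx = skeleton.atom_indices
    g.add_nodes_from(idx)
    for b in skeleton.graph.bonds:
        g.add_edge(idx[b.i], idx[b.j])
    return g


def _constraint_holds(
    constraint: PatternConstraint,
    mapping: Mapping[int, int],
    pos_to_ref: Mapping[int, int],
    original: MolecularGraph,
) -> bool:
    atoms = [mapping[pos_to_ref[p]] for p in constraint.positions]
    if constraint.kind == DOUBLE_BOND:
        i, j = atoms
        return original.bond_order(i, j) == 2
    if constraint.kind == EPOXIDE_BRIDGE:
        i, j = atoms
        if original.bond_order(i, j) != 1:
            return False
        common = set(original.neighbors(i)) & set(original.neighbors(j))
        return any(
            original.element(o) == "O"
            and original.bond_order(i, o) == 1
            and original.bond_order(j, o) == 1
            for o in common
        )
    raise ValueError(f"unknown constraint kind {constraint.kind!r}")


def compound_matches_pattern(
    compound: CompoundRecord,
    assignment: SkeletonAssignment,
    library: SkeletonLibrary,
    query: PatternQuery,
) -> bool:
    """Existential pattern match of one compound against one query."""
    ref_sk, numbering = library.get(query.skeleton_scope)
    pos_to_ref = {pos: idx for idx, pos in numbering.items()}
    for c in query.solid_constraints():
        for p in c.positions:
            if p not in pos_to_ref:
                raise KeyError(
                    f"position {p} absent from numbering of "
                    f"{query.skeleton_scope!r}"
                )
    if assignment.skeleton.skeleton_id != ref_sk.skeleton_id:
        return False
    solids = query.solid_constraints()
    if not solids:
        return True
    ref_g = ref_sk.graph.to_networkx()
    frag_g = _fragment_nx(assignment.skeleton)
    matcher = nx.algorithms.isomorphism.GraphMatcher(ref_g, frag_g)
    for mapping in matcher.isomorphisms_iter():
        if all(
            _constraint_holds(c, mapping, pos_to_ref, compound.graph)
            for c in solids
        ):
            return True
    return False


def positional_pattern_count(
    compounds: Iterable[CompoundRecord],
    assignments: Mapping[str, SkeletonAssignment],
    library: SkeletonLibrary,
    query: PatternQuery,
    occurrence: Optional[pd.DataFrame] = None,
) -> tuple[int, pd.DataFrame]:
    """Count compounds matching a positional pattern query.

    Returns the total count and, when an occurrence table is supplied, a
    per-clade breakdown (distinct matching compounds reported from each
    clade).  Each compound counts at most once regardless of how many
    skeleton automorphisms satisfy the constraints.
    """
    matched: set[str] = set()
    for comp in compounds:
        a = assignments.get(comp.compound_id)
        if a is None:
            continue
        if compound_matches_pattern(comp, a, library, query):
            matched.add(comp.compound_id)
    if occurrence is None or occurrence.empty:
        per_clade = pd.DataFrame(columns=["clade", "n_compounds"])
    else:
        sub = occurrence[occurrence["compound_id"].isin(matched)]
        per_clade = (
            sub.groupby("clade")["compound_id"]
            .nunique()
            .rename("n_compounds")
            .reset_index()
            .sort_values("clade")
            .reset_index(drop=True)
        )
    return len(matched), per_clade


def default_queries() -> list[PatternQuery]:
    """The shipped positional queries for labdane/clerodane desaturation and
    epoxide patterns; user-editable via YAML."""
    return [
        PatternQuery(
            "delta-7 labdane", "Sk4 labdane",
            [PatternConstraint((7, 8), DOUBLE_BOND)],
        ),
        PatternQuery(
            "delta-8(9) labdane", "Sk4 labdane",
            [PatternConstraint((8, 9), DOUBLE_BOND)],
        ),
        PatternQuery(
            "delta-3 clerodane", "Sk2 clerodane",
            [PatternConstraint((3, 4), DOUBLE_BOND)],
        ),
        PatternQuery(
            "delta-4(18) clerodane", "Sk2 clerodane",
            [PatternConstraint((4, 18), DOUBLE_BOND)],
        ),
        PatternQuery(
            "4(18)-epoxy clerodane", "Sk2 clerodane",
            [PatternConstraint((4, 18), EPOXIDE_BRIDGE)],
        ),
    ]


def load_queries(path: str | Path) -> list[PatternQuery]:
    """Read pattern queries from YAML (name, scope, constraints)."""
    data = yaml.safe_load(Path(path).read_text())
    queries = []
    for q in data:
        constraints = [
            PatternConstraint(
                tuple(int(p) for p in c["positions"]),
                c["kind"],
                bool(c.get("solid", True)),
            )
            for c in q.get("constraints", [])
        ]
        queries.append(PatternQuery(q["name"], q["scope"], constraints))
    return queries


def save_queries(queries: Sequence[PatternQuery], path: str | Path) -> None:
    data = [
        {
            "name": q.name,
            "scope": q.skeleton_scope,
            "constraints": [
                {
                    "positions": list(c.positions),
                    "kind": c.kind,
                    "solid": c.solid,
                }
                for c in q.constraints
            ],
        }
        for q in queries
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
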