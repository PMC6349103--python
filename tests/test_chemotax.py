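"""Occurrence merging, distribution marginals and pattern queries."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from skeletax.chemotax import (
    DOUBLE_BOND,
    EPOXIDE_BRIDGE,
    PatternConstraint,
    PatternQuery,
    compound_matches_pattern,
    database_overlap,
    default_queries,
    load_queries,
    merge_occurrences,
    positional_pattern_count,
    save_queries,
    skeleton_distribution,
    unknown_route_skeletons,
)
from skeletax.graph import mol_from_graph
from skeletax.skeleton import extract_skeleton
from skeletax.taxonomy import CladeMap, TaxonRecord

from conftest import compound_from_positions


REFERENCE = [
    TaxonRecord(10, "Salvia", "genus"),
    TaxonRecord(11, "Salvia officinalis", "species", 10),
    TaxonRecord(12, "Salvia miltiorrhiza", "species", 10),
    TaxonRecord(20, "Ajuga", "genus"),
    TaxonRecord(21, "Ajuga reptans", "species", 20),
    TaxonRecord(30, "Marrubium", "genus"),
    TaxonRecord(31, "Marrubium vulgare", "species", 30),
]
CLADES = CladeMap(
    [("Salvia", "Nepetoideae"), ("Ajuga", "Ajugoideae"),
     ("Marrubium", "Lamioideae")]
)


def occ_frame(rows):
    return pd.DataFrame(
        rows, columns=["compound_id", "taxon_id", "genus", "clade",
                       "source_db"]
    )


class TestMergeOccurrences:
    def test_shared_record_keeps_both_source_rows(self):
        src = {
            "DNP-like": pd.DataFrame(
                {"compound_id": ["c1"], "taxon_id": [11]}
            ),
            "SISTEMAT-like": pd.DataFrame(
                {"compound_id": ["c1"], "taxon_id": [11]}
            ),
        }
        occ = merge_occurrences(src, REFERENCE, CLADES)
        assert len(occ) == 2
        assert set(occ["source_db"]) == {"DNP-like", "SISTEMAT-like"}
        assert set(occ["genus"]) == {"salvia"}
        assert set(occ["clade"]) == {"Nepetoideae"}

    def test_empty_sources(self):
        occ = merge_occurrences({}, REFERENCE, CLADES)
        assert occ.empty

    def test_unresolved_taxa_excluded(self, caplog):
        src = {
            "DNP-like": pd.DataFrame(
                {"compound_id": ["c1", "c2"], "taxon_id": [11, 999]}
            )
        }
        occ = merge_occurrences(src, REFERENCE, CLADES)
        assert list(occ["compound_id"]) == ["c1"]

    def test_union_equals_brute_force(self):
        rng = np.random.default_rng(8)
        taxa = [11, 12, 21, 31]
        per_source = {}
        for s in ("DNP-like", "SISTEMAT-like", "NAPRALERT-like"):
            rows = {
                (f"c{int(rng.integers(5))}", int(rng.choice(taxa)))
                for _ in range(12)
            }
            per_source[s] = pd.DataFrame(
                sorted(rows), columns=["compound_id", "taxon_id"]
            )
        occ = merge_occurrences(per_source, REFERENCE, CLADES)
        expected = {
            (c, t, s)
            for s, df in per_source.items()
            for c, t in df.itertuples(index=False)
        }
        got = set(
            zip(occ["compound_id"], occ["taxon_id"], occ["source_db"])
        )
        assert got == expected


class TestSkeletonDistribution:
    def _assignments(self, library, spec):
        out = {}
        for cid, template in spec.items():
            comp = compound_from_positions(cid, template)
            out[cid] = extract_skeleton(comp, library)
        return out

    def test_single_compound_three_genera_two_clades(self, library):
        occ = occ_frame(
            [
                ("c1", 11, "salvia", "Nepetoideae", "DNP-like"),
                ("c1", 21, "ajuga", "Ajugoideae", "DNP-like"),
                ("c1", 31, "marrubium", "Lamioideae", "DNP-like"),
            ]
        )
        occ.loc[2, "clade"] = "Ajugoideae"  # 3 genera, 2 clades
        assignments = self._assignments(library, {"c1": "Sk4 labdane"})
        dist = skeleton_distribution(occ, assignments)
        row = dist.per_skeleton.iloc[0]
        assert (row["n_compounds"], row["n_genera"], row["n_clades"]) == (
            1, 3, 2
        )

    def test_missing_assignment_error_names_compounds(self, library):
        occ = occ_frame([("cX", 11, "salvia", "Nepetoideae", "DNP-like")])
        with pytest.raises(KeyError, match="cX"):
            skeleton_distribution(occ, {})

    def test_name_only_source_counts_structures_not_skeletons(self, library):
        occ = occ_frame(
            [
                ("c1", 11, "salvia", "Nepetoideae", "DNP-like"),
                ("name-compound", 11, "salvia", "Nepetoideae",
                 "NAPRALERT-like"),
            ]
        )
        assignments = self._assignments(library, {"c1": "Sk4 labdane"})
        dist = skeleton_distribution(occ, assignments)
        genus_row = dist.per_genus.iloc[0]
        assert genus_row["n_compounds"] == 2   # includes the name-only record
        assert genus_row["n_skeletons"] == 1
        assert dist.per_skeleton["n_compounds"].sum() == 1

    def test_counting_consistency_and_monotonicity(self, library):
        assignments = self._assignments(
            library,
            {"c1": "Sk4 labdane", "c2": "Sk4 labdane", "c3": "Sk2 clerodane"},
        )
        rows = [
            ("c1", 11, "salvia", "Nepetoideae", "DNP-like"),
            ("c2", 21, "ajuga", "Ajugoideae", "DNP-like"),
            ("c3", 11, "salvia", "Nepetoideae", "DNP-like"),
        ]
        dist = skeleton_distribution(occ_frame(rows), assignments)
        assert dist.per_skeleton["n_compounds"].sum() == 3
        # adding a row never decreases any marginal cell
        more = rows + [("c3", 31, "marrubium", "Lamioideae", "DNP-like")]
        dist2 = skeleton_distribution(occ_frame(more), assignments)
        a = dist.per_skeleton.set_index("skeleton_id")
        b = dist2.per_skeleton.set_index("skeleton_id")
        assert (b.loc[a.index, "n_genera"] >= a["n_genera"]).all()
        assert (b.loc[a.index, "n_clades"] >= a["n_clades"]).all()


class TestUnknownRoute:
    def test_set_difference(self, library):
        comps = {
            f"c{i}": t
            for i, t in enumerate(
                ["Sk1 kaurane", "Sk2 clerodane", "Sk3 abietane",
                 "Sk4 labdane", "Sk6 pimarane", "Sk14 atisane"]
            )
        }
        assignments = {
            cid: extract_skeleton(
                compound_from_positions(cid, t), library
            )
            for cid, t in comps.items()
        }
        occ = occ_frame(
            [
                (cid, 11, "salvia", "Nepetoideae", "DNP-like")
                for cid in comps
            ]
        )
        dist = skeleton_distribution(occ, assignments)
        known = pd.DataFrame(
            {
                "enzyme": ["E1", "E2"],
                "product": ["p1", "p2"],
                "product_skeleton": ["Sk4 labdane", "Sk2 clerodane"],
            }
        )
        unknown = unknown_route_skeletons(dist, known, library)
        assert len(unknown) == 4
        lab, _ = library.get("Sk4 labdane")
        assert lab.skeleton_id not in unknown

    def test_disjoint_known_set_returns_all(self, library):
        assignments = {
            "c1": extract_skeleton(
                compound_from_positions("c1", "Sk1 kaurane"), library
            )
        }
        occ = occ_frame([("c1", 11, "salvia", "Nepetoideae", "DNP-like")])
        dist = skeleton_distribution(occ, assignments)
        known = pd.DataFrame(
            {"enzyme": ["E"], "product": ["p"],
             "product_skeleton": ["Sk4 labdane"]}
        )
        assert unknown_route_skeletons(dist, known, library) == (
            dist.observed_skeletons()
        )


class TestDatabaseOverlap:
    def test_identical_sources_full_intersection(self):
        rows = [
            ("c1", 11, "salvia", "Nepetoideae", "DNP-like"),
            ("c2", 11, "salvia", "Nepetoideae", "DNP-like"),
            ("c1", 11, "salvia", "Nepetoideae", "SISTEMAT-like"),
            ("c2", 11, "salvia", "Nepetoideae", "SISTEMAT-like"),
        ]
        table = database_overlap(occ_frame(rows))
        row = table.iloc[0]
        assert row["n_a"] == row["n_b"] == row["n_both"] == 2

    def test_disjoint_sources_zero_intersection(self):
        rows = [
            ("c1", 11, "salvia", "Nepetoideae", "DNP-like"),
            ("c2", 11, "salvia", "Nepetoideae", "SISTEMAT-like"),
        ]
        assert database_overlap(occ_frame(rows))["n_both"].iloc[0] == 0

    def test_single_source_errors(self):
        rows = [("c1", 11, "salvia", "Nepetoideae", "DNP-like")]
        with pytest.raises(ValueError, match="two sources"):
            database_overlap(occ_frame(rows))

    def test_equals_brute_force_pairwise_intersections(self):
        rng = np.random.default_rng(31)
        sources = ["DNP-like", "SISTEMAT-like", "NAPRALERT-like"]
        rows = {
            (
                f"c{int(rng.integers(8))}",
                11,
                "salvia",
                "Nepetoideae",
                str(rng.choice(sources)),
            )
            for _ in range(40)
        }
        occ = occ_frame(sorted(rows))
        table = database_overlap(occ)
        for r in table.itertuples(index=False):
            set_a = {
                c for c, *_, s in rows if s == r.source_a
            }
            set_b = {
                c for c, *_, s in rows if s == r.source_b
            }
            assert r.n_both == len(set_a & set_b)


def oracle_pattern_match(compound, assignment, library, query):
    """Independent all-mappings oracle via RDKit substructure matching.

    Enumerates every isomorphism of the reference skeleton onto the
    compound's extracted skeleton fragment with GetSubstructMatches
    (uniquify off), then checks each solid constraint in the original
    graph by direct adjacency inspection.
    """
    ref_sk, numbering = library.get(query.skeleton_scope)
    if assignment.skeleton.skeleton_id != ref_sk.skeleton_id:
        return False
    frag = assignment.skeleton
    frag_mol = mol_from_graph(frag.graph)
    ref_mol = mol_from_graph(ref_sk.graph)
    matches = frag_mol.GetSubstructMatches(
        ref_mol, uniquify=False, maxMatches=100000
    )
    pos_to_ref = {pos: idx for idx, pos in numbering.items()}
    g = compound.graph
    solids = [c for c in query.constraints if c.solid and c.kind != "any"]
    if not solids:
        return len(matches) > 0
    for match in matches:  # match[ref_idx] = fragment-local atom idx
        ok = True
        for c in solids:
            orig = [
                frag.atom_indices[match[pos_to_ref[p]]] for p in c.positions
            ]
            if c.kind == DOUBLE_BOND:
                i, j = orig
                ok = g.bond_order(i, j) == 2
            elif c.kind == EPOXIDE_BRIDGE:
                i, j = orig
                shared = set(g.neighbors(i)) & set(g.neighbors(j))
                ok = g.bond_order(i, j) == 1 and any(
                    g.element(o) == "O" for o in shared
                )
            if not ok:
                break
        if ok:
            return True
    return False


class TestPatternQueries:
    def _labdane_7ene(self):
        return compound_from_positions(
            "lab-7ene", "Sk4 labdane", double_bonds=[(7, 8)],
            hydroxyls=[15],
        )

    def test_delta7_labdane_matches(self, library):
        comp = self._labdane_7ene()
        a = extract_skeleton(comp, library)
        q = PatternQuery(
            "delta-7 labdane", "Sk4 labdane",
            [PatternConstraint((7, 8), DOUBLE_BOND)],
        )
        assert compound_matches_pattern(comp, a, library, q)

    def test_delta8_9_solid_rejects_7ene(self, library):
        comp = self._labdane_7ene()
        a = extract_skeleton(comp, library)
        q = PatternQuery(
            "delta-8(9) labdane", "Sk4 labdane",
            [PatternConstraint((8, 9), DOUBLE_BOND)],
        )
        assert not compound_matches_pattern(comp, a, library, q)

    def test_saturated_skeleton_never_matches_solid_double_bond(
        self, library
    ):
        comp = compound_from_positions("plain", "Sk2 clerodane")
        a = extract_skeleton(comp, library)
        for q in default_queries():
            if q.skeleton_scope != "Sk2 clerodane":
                continue
            if any(c.kind == DOUBLE_BOND for c in q.constraints):
                assert not compound_matches_pattern(comp, a, library, q)

    def test_epoxide_bridge_detected(self, library):
        comp = compound_from_positions(
            "epoxy", "Sk2 clerodane", epoxides=[(4, 18)]
        )
        a = extract_skeleton(comp, library)
        q = PatternQuery(
            "4(18)-epoxy clerodane", "Sk2 clerodane",
            [PatternConstraint((4, 18), EPOXIDE_BRIDGE)],
        )
        assert compound_matches_pattern(comp, a, library, q)
        # a 4(18) double bond is not an epoxide
        comp2 = compound_from_positions(
            "ene", "Sk2 clerodane", double_bonds=[(4, 18)]
        )
        a2 = extract_skeleton(comp2, library)
        assert not compound_matches_pattern(comp2, a2, library, q)

    def test_wrong_scope_never_matches(self, library):
        comp = self._labdane_7ene()
        a = extract_skeleton(comp, library)
        q = PatternQuery(
            "delta-3 clerodane", "Sk2 clerodane",
            [PatternConstraint((3, 4), DOUBLE_BOND)],
        )
        assert not compound_matches_pattern(comp, a, library, q)

    def test_invalid_position_raises(self, library):
        comp = self._labdane_7ene()
        a = extract_skeleton(comp, library)
        q = PatternQuery(
            "bad", "Sk4 labdane",
            [PatternConstraint((7, 99), DOUBLE_BOND)],
        )
        with pytest.raises(KeyError, match="99"):
            compound_matches_pattern(comp, a, library, q)

    def test_matches_all_mapping_oracle_on_decorated_fixtures(
        self, library
    ):
        rng = np.random.default_rng(19)
        fixtures = []
        bonds_by_template = {
            "Sk4 labdane": [(7, 8), (8, 9), (11, 12), (13, 14), (14, 15)],
            "Sk2 clerodane": [(3, 4), (4, 18), (13, 14), (7, 8)],
        }
        i = 0
        for template, bonds in bonds_by_template.items():
            for _ in range(15):
                k = int(rng.integers(0, 3))
                picks = []
                used_positions: set[int] = set()
                for j in rng.choice(len(bonds), size=k, replace=False):
                    b = bonds[int(j)]
                    if used_positions & set(b):
                        continue  # keep carbon valences legal
                    picks.append(b)
                    used_positions.update(b)
                dbl, epox = [], []
                for b in picks:
                    (epox if rng.random() < 0.3 else dbl).append(b)
                fixtures.append(
                    compound_from_positions(
                        f"f{i}", template, double_bonds=dbl, epoxides=epox,
                        hydroxyls=[2] if rng.random() < 0.5 else [],
                    )
                )
                i += 1
        assert len(fixtures) >= 30
        for comp in fixtures:
            a = extract_skeleton(comp, library)
            for q in default_queries():
                got = compound_matches_pattern(comp, a, library, q)
                expected = oracle_pattern_match(comp, a, library, q)
                assert got == expected, (comp.compound_id, q.name)

    def test_count_once_with_per_clade_breakdown(self, library):
        comps = [
            self._labdane_7ene(),
            compound_from_positions("lab-plain", "Sk4 labdane"),
        ]
        assignments = {
            c.compound_id: extract_skeleton(c, library) for c in comps
        }
        occ = occ_frame(
            [
                ("lab-7ene", 11, "salvia", "Nepetoideae", "DNP-like"),
                ("lab-7ene", 12, "salvia", "Nepetoideae", "SISTEMAT-like"),
                ("lab-7ene", 21, "ajuga", "Ajugoideae", "DNP-like"),
                ("lab-plain", 31, "marrubium", "Lamioideae", "DNP-like"),
            ]
        )
        q = PatternQuery(
            "delta-7 labdane", "Sk4 labdane",
            [PatternConstraint((7, 8), DOUBLE_BOND)],
        )
        n, per_clade = positional_pattern_count(
            comps, assignments, library, q, occ
        )
        assert n == 1
        got = dict(zip(per_clade["clade"], per_clade["n_compounds"]))
        assert got == {"Ajugoideae": 1, "Nepetoideae": 1}

    def test_query_yaml_roundtrip(self, tmp_path):
        queries = default_queries()
        path = tmp_path / "queries.yaml"
        save_queries(queries, path)
        back = load_queries(path)
        assert [q.name for q in back] == [q.name for q in queries]
        assert back[0].constraints == queries[0].constraints
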