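"""Shared fixtures: reference library and position-numbered test compounds."""

from __future__ import annotations

import pytest

from skeletax.chem_io import CompoundRecord, standardize
from skeletax.graph import Atom, Bond, MolecularGraph
from skeletax.skeleton import REFERENCE_SKELETON_EDGES, default_library
from skeletax.synthetic_data import (  # re-exported for test modules
    permute_graph,
    random_carbon_fragment_graph,
    random_molecular_graph,
)

SCLAREOL_SMILES = "CC1(C)CCCC2(C)C1CCC(C)(O)C2CCC(C)(O)C=C"
SCLAREOL_STEREO_SMILES = (
    "CC1(C)CCC[C@]2(C)[C@@H]1CC[C@](C)(O)[C@H]2CC[C@](C)(O)C=C"
)

__all__ = [
    "SCLAREOL_SMILES",
    "SCLAREOL_STEREO_SMILES",
    "compound_from_positions",
    "permute_graph",
    "random_carbon_fragment_graph",
    "random_molecular_graph",
    "library",
]


@pytest.fixture(scope="session")
def library():
    return default_library()


def compound_from_positions(
    compound_id: str,
    template: str,
    double_bonds: list[tuple[int, int]] = (),
    epoxides: list[tuple[int, int]] = (),
    hydroxyls: list[int] = (),
    drop_positions: list[int] = (),
) -> CompoundRecord:
    """Build a test compound from a reference skeleton's position numbering.

    ``double_bonds``/``epoxides``/``hydroxyls`` are given in diterpene
    position numbers; ``drop_positions`` removes atoms (for nor-skeletons).
    """
    edges = REFERENCE_SKELETON_EDGES[template]
    keep = sorted({v for e in edges for v in e} - set(drop_positions))
    remap = {p: i for i, p in enumerate(keep)}
    atoms = [Atom(i, "C") for i in range(len(keep))]
    dbl = {tuple(sorted(d)) for d in double_bonds}
    bonds = []
    for i, j in edges:
        if i in remap and j in remap:
            order = 2 if tuple(sorted((i, j))) in dbl else 1
            bonds.append(Bond(remap[i], remap[j], order))
    next_idx = len(atoms)
    for p, q in epoxides:
        atoms.append(Atom(next_idx, "O"))
        bonds.append(Bond(remap[p], next_idx, 1))
        bonds.append(Bond(remap[q], next_idx, 1))
        next_idx += 1
    for p in hydroxyls:
        atoms.append(Atom(next_idx, "O"))
        bonds.append(Bond(remap[p], next_idx, 1))
        next_idx += 1
    graph = MolecularGraph(atoms, bonds)
    graph.validate()
    return CompoundRecord(
        compound_id=compound_id, graph=standardize(graph),
        source_db="synthetic",
    )
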