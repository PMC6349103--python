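"""Element- and bond-order-labeled molecular graphs.

The package works on a deliberately minimal graph representation: atoms are
(index, element, formal_charge) triples, bonds are (i, j, order) triples with
order in {1, 2, 3, "aromatic"}, and hydrogens are always implicit.  This is
the common currency between structure parsing, skeleton extraction and
pattern matching; RDKit molecules are converted to and from it at the
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from rdkit import Chem

AROMATIC = "aromatic"

_RDKIT_ORDER = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    AROMATIC: Chem.BondType.AROMATIC,
}
_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: AROMATIC,
}


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    formal_charge: int = 0


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: object  # 1 | 2 | 3 | "aromatic"

    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class MolecularGraph:
    """An undirected molecular graph with implicit hydrogens.

    Invariants (checked by :meth:`validate`): atom indices are unique and
    contiguous from 0; no self loops; at most one bond per atom pair.
    Connected components are implicit in the bond list.
    """

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    def validate(self) -> None:
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(indices))):
            raise ValueError("atom indices must be contiguous from 0")
        seen: set[tuple[int, int]] = set()
        n = len(indices)
        for b in self.bonds:
            if b.i == b.j:
                raise ValueError(f"self-loop bond on atom {b.i}")
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references missing atom")
            if b.key() in seen:
                raise ValueError(f"duplicate bond {b.key()}")
            seen.add(b.key())

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def n_carbons(self) -> int:
        return sum(1 for a in self.atoms if a.element == "C")

    def element(self, i: int) -> str:
        return self.atoms[i].element

    def bond_order(self, i: int, j: int) -> object | None:
        key = (i, j) if i < j else (j, i)
        for b in self.bonds:
            if b.key() == key:
                return b.order
        return None

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element, charge=a.formal_charge)
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order)
        return g

    def subgraph(self, indices: Sequence[int]) -> "MolecularGraph":
        """Induced subgraph, reindexed to 0..k-1 preserving input order."""
        remap = {old: new for new, old in enumerate(indices)}
        atoms = [
            Atom(remap[a.index], a.element, a.formal_charge)
            for a in self.atoms
            if a.index in remap
        ]
        atoms.sort(key=lambda a: a.index)
        bonds = [
            Bond(remap[b.i], remap[b.j], b.order)
            for b in self.bonds
            if b.i in remap and b.j in remap
        ]
        return MolecularGraph(atoms, bonds)

    def connected_components(self) -> list[list[int]]:
        comps = nx.connected_components(self.to_networkx())
        return [sorted(c) for c in comps]


def graph_from_mol(mol: Chem.Mol) -> MolecularGraph:
    """Convert an RDKit molecule (implicit-H form) to a MolecularGraph."""
    # sanitize=False: keep whatever Kekulé/aromatic state the caller set
    mol = Chem.RemoveHs(mol, sanitize=False)
    atoms = [
        Atom(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge())
        for a in mol.GetAtoms()
    ]
    bonds = [
        Bond(
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _ORDER_FROM_RDKIT[b.GetBondType()],
        )
        for b in mol.GetBonds()
    ]
    g = MolecularGraph(atoms, bonds)
    g.validate()
    return g


def mol_from_graph(graph: MolecularGraph, sanitize: bool = True) -> Chem.Mol:
    """Rebuild an RDKit molecule from a MolecularGraph."""
    rw = Chem.RWMol()
    for a in graph.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.formal_charge)
        rw.AddAtom(atom)
    for b in graph.bonds:
        rw.AddBond(int(b.i), int(b.j), _RDKIT_ORDER[b.order])
    mol = rw.GetMol()
    if sanitize:
        Chem.SanitizeMol(mol)
    return mol


def carbon_graph(edges: Iterable[tuple[int, int]]) -> MolecularGraph:
    """Build an all-carbon, all-single-bond graph from an edge list.

    Node labels in ``edges`` may be arbitrary hashables (e.g. diterpene
    position numbers 1..20); they are mapped to contiguous indices in sorted
    order, so position *k* becomes atom index *k-1* for 1..n numbering.
    """
    nodes = sorted({v for e in edges for v in e})
    remap = {v: i for i, v in enumerate(nodes)}
    atoms = [Atom(i, "C") for i in range(len(nodes))]
    bonds = [Bond(remap[i], remap[j], 1) for i, j in edges]
    g = MolecularGraph(atoms, bonds)
    g.validate()
    return g


def graphs_isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Element- and order-aware graph isomorphism (VF2 via networkx)."""
    return nx.is_isomorphic(
        a.to_networkx(),
        b.to_networkx(),
        node_match=lambda x, y: x["element"] == y["element"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )
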