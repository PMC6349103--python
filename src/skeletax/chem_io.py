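"""Structure parsing, standardization and tabular I/O.

Natural-product occurrence databases deliver structures as SMILES or InChI
strings (sometimes SDF).  Everything downstream — skeleton extraction,
pattern queries — operates on stereochemistry-free molecular graphs, so this
module parses, drops stereo/isotope annotations, fixes a deterministic
Kekulé assignment for aromatic systems, and hands out
:class:`~skeletax.graph.MolecularGraph` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import inchi as rd_inchi

from .graph import MolecularGraph, graph_from_mol, mol_from_graph

log = logging.getLogger(__name__)

# RDKit is chatty about bad records; we raise structured errors instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

SOURCE_TAGS = ("DNP-like", "SISTEMAT-like", "NAPRALERT-like", "synthetic")


class StructureParseError(ValueError):
    """Raised when a structure string cannot be parsed.

    Carries the offending text and, when known, the record id so that batch
    pipelines can log and skip rather than abort.
    """

    def __init__(self, text: str, fmt: str, record_id: str | None = None):
        self.text = text
        self.fmt = fmt
        self.record_id = record_id
        where = f" (record {record_id})" if record_id else ""
        super().__init__(f"unparsable {fmt} string{where}: {text!r}")


@dataclass
class CompoundRecord:
    compound_id: str
    name: str = ""
    structure_text: str = ""
    graph: Optional[MolecularGraph] = None
    source_db: str = "synthetic"
    taxa: list[str] = field(default_factory=list)


def parse_structure(text: str, format: str = "smiles") -> MolecularGraph:
    """Parse a SMILES or InChI string into a MolecularGraph.

    Stereochemistry cannot be represented in the graph and is therefore
    discarded at this boundary; aromatic bonds are carried through as-is and
    normalized by :func:`standardize`.
    """
    if not text or not text.strip():
        raise StructureParseError(text, format)
    fmt = format.lower()
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(text)
    elif fmt == "inchi":
        mol = rd_inchi.MolFromInchi(text, treatWarningAsError=False)
    else:
        raise ValueError(f"unknown structure format: {format!r}")
    if mol is None:
        raise StructureParseError(text, fmt)
    return graph_from_mol(mol)


def standardize(graph: MolecularGraph) -> MolecularGraph:
    """Normalize a molecular graph to the package's internal convention.

    Stereo and isotope annotations are already absent from the graph form;
    this step fixes a deterministic Kekulé structure for aromatic systems
    (so every downstream consumer sees integer bond orders), keeps formal
    charges on atoms, collapses explicit hydrogens, and retains
    multi-component inputs (salts, mixtures) as one graph with several
    connected components.  Idempotent.
    """
    mol = mol_from_graph(graph)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return graph_from_mol(mol)


def to_smiles(graph: MolecularGraph) -> str:
    """Canonical SMILES of a (standardized) graph, without stereo."""
    mol = mol_from_graph(graph)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_structure_file(
    path: str | Path,
    format: str,
    source_db: str = "synthetic",
    skip_bad: bool = True,
) -> list[CompoundRecord]:
    """Read SMILES/InChI lists (one per line, optional leading tab-separated
    id) or an SDF (V2000) into CompoundRecords with standardized graphs.

    Records that fail to parse are logged and skipped when ``skip_bad`` is
    true (occurrence databases routinely contain a few broken entries);
    their ``graph`` stays ``None`` otherwise.
    """
    path = Path(path)
    fmt = format.lower()
    records: list[CompoundRecord] = []
    if fmt in ("smiles", "inchi"):
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                cid, text = line.split("\t", 1)
            else:
                cid, text = f"{path.stem}_{lineno}", line
            rec = CompoundRecord(cid, structure_text=text, source_db=source_db)
            try:
                rec.graph = standardize(parse_structure(text, fmt))
            except StructureParseError as exc:
                if not skip_bad:
                    raise StructureParseError(text, fmt, cid) from exc
                log.warning("skipping unparsable record %s: %r", cid, text)
                continue
            records.append(rec)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                log.warning("skipping unparsable SDF record #%d", i)
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            cid = cid or f"{path.stem}_{i + 1}"
            rec = CompoundRecord(
                cid,
                structure_text=Chem.MolToSmiles(mol),
                source_db=source_db,
            )
            rec.graph = standardize(graph_from_mol(mol))
            records.append(rec)
    else:
        raise ValueError(f"unknown input format: {format!r}")
    return records


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_table(rows: Iterable, path: str | Path) -> pd.DataFrame:
    """Write a homogeneous sequence of records (dataclasses, dicts or a
    DataFrame) to CSV with a stable column order; returns the frame written.

    All rows must share one schema; mixed schemas are an error.  An empty
    input with no discoverable schema produces a header-only CSV only when a
    DataFrame (which carries its columns) is supplied.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        dicts = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                d = {k: getattr(r, k) for k in r.__dataclass_fields__}
            elif isinstance(r, dict):
                d = dict(r)
            else:
                raise TypeError(f"unsupported record type: {type(r)!r}")
            dicts.append(d)
        if dicts:
            schema = list(dicts[0].keys())
            for d in dicts[1:]:
                if list(d.keys()) != schema:
                    raise ValueError("records have mixed schemas")
        df = pd.DataFrame(dicts)
    df.to_csv(path, index=False)
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
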