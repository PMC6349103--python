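"""Taxon-name resolution and clade assignment.

Occurrence databases report organism names as free text ("Salvia
officinalis L.", "Plectranthus barbatus (syn. Coleus forskohlii)", hybrid
marks, varieties...).  This module normalizes such strings, resolves them
against a reference taxonomy (NCBI-TaxID-like records), and assigns genera
to one of the 12 primary monophyletic Lamiaceae clades used for
chemotaxonomic annotation.

Resolution is staged: exact byte-for-byte match, then match on normalized
names, then fuzzy match by normalized edit similarity with a configurable
threshold — fuzzy hits carry a review flag, mechanizing what was once a
manual-inspection step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import pandas as pd

#: tokens that never belong to a binomial (markers, rank qualifiers)
_MARKER_TOKENS = {
    "syn.", "syn", "cf.", "cf", "var.", "var", "aff.", "aff",
    "subsp.", "subsp", "ssp.", "ssp", "f.", "sp.", "sp", "×", "x",
}


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: int
    canonical_name: str
    rank: str  # "genus" | "species"
    parent_genus_id: Optional[int] = None


@dataclass
class NameResolution:
    raw_name: str
    taxon_id: Optional[int]
    method: str  # exact | normalized | fuzzy | unmatched
    genus: str
    similarity: float = 1.0
    needs_review: bool = False


class CladeMap:
    """genus -> clade lookup over a closed set of at most 12 clade labels."""

    def __init__(self, rows: Iterable[tuple[str, str]]):
        self._map: dict[str, str] = {}
        for genus, clade in rows:
            key = genus.strip().lower()
            if key in self._map and self._map[key] != clade:
                raise ValueError(f"conflicting clade for genus {genus!r}")
            self._map[key] = clade
        clades = set(self._map.values())
        if len(clades) > 12:
            raise ValueError(f"{len(clades)} clades exceed the closed set of 12")

    def clades(self) -> set[str]:
        return set(self._map.values())

    def items(self) -> list[tuple[str, str]]:
        return sorted(self._map.items())

    def assign(self, genus: str) -> str:
        return self._map.get(genus.strip().lower(), "unassigned")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CladeMap":
        df = pd.read_csv(path)
        return cls(zip(df["genus"], df["clade"]))


def assign_clade(genus: str, clade_map: "CladeMap") -> str:
    """Clade of a genus, or "unassigned"; case-insensitive on the genus."""
    return clade_map.assign(genus)


def normalize_name(raw: str) -> str:
    """Normalize a raw taxon-name string to at most a lowercase binomial.

    Lowercases, collapses whitespace, drops parenthesized synonym blocks,
    drops marker tokens (syn./cf./var./hybrid signs) and everything after
    them at rank level, strips authority abbreviations, and keeps the first
    two remaining tokens.  Returns "" when nothing survives.
    """
    s = re.sub(r"\([^)]*\)", " ", raw)  # parenthesized synonyms/authorities
    s = s.replace("×", " ")
    s = re.sub(r"\s+", " ", s).strip().lower()
    tokens = []
    for tok in s.split(" "):
        if tok in _MARKER_TOKENS:
            continue
        tokens.append(tok)
        if len(tokens) == 2:
            break
    # a trailing single-letter authority like "l." can survive as token 2
    if len(tokens) == 2 and re.fullmatch(r"[a-z]{1,2}\.", tokens[1]):
        tokens = tokens[:1]
    return " ".join(tokens)


def edit_similarity(a: str, b: str) -> float:
    """1 - levenshtein(a, b) / max(len); 1.0 for two empty strings."""
    if not a and not b:
        return 1.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def resolve_taxon(
    raw: str,
    reference: Sequence[TaxonRecord],
    fuzzy_threshold: float = 0.9,
) -> NameResolution:
    """Resolve one raw name against the reference taxonomy.

    Preference order is strict: exact > normalized > fuzzy; an exact match
    is always taken when one exists.  Fuzzy matches are flagged for review.
    Unmatched is a valid outcome (method="unmatched", taxon_id=None).
    """
    if not reference:
        raise ValueError("reference taxonomy is empty")
    norm = normalize_name(raw)
    for rec in reference:
        if rec.canonical_name == raw:
            return NameResolution(
                raw, rec.taxon_id, "exact", _genus_of(rec, reference)
            )
    if norm:
        for rec in reference:
            if normalize_name(rec.canonical_name) == norm:
                return NameResolution(
                    raw, rec.taxon_id, "normalized", _genus_of(rec, reference)
                )
        best: Optional[TaxonRecord] = None
        best_sim = -1.0
        for rec in reference:
            sim = edit_similarity(norm, normalize_name(rec.canonical_name))
            if sim > best_sim or (
                sim == best_sim
                and best is not None
                and (rec.canonical_name, rec.taxon_id)
                < (best.canonical_name, best.taxon_id)
            ):
                best, best_sim = rec, sim
        if best is not None and best_sim >= fuzzy_threshold:
            return NameResolution(
                raw,
                best.taxon_id,
                "fuzzy",
                _genus_of(best, reference),
                similarity=best_sim,
                needs_review=True,
            )
    genus = norm.split(" ")[0] if norm else ""
    return NameResolution(raw, None, "unmatched", genus)


def _genus_of(rec: TaxonRecord, reference: Sequence[TaxonRecord]) -> str:
    if rec.rank == "genus":
        return rec.canonical_name.split(" ")[0].lower()
    if rec.parent_genus_id is not None:
        for r in reference:
            if r.taxon_id == rec.parent_genus_id:
                return r.canonical_name.split(" ")[0].lower()
    return rec.canonical_name.split(" ")[0].lower()


def resolve_all(
    names: Iterable[str],
    reference: Sequence[TaxonRecord],
    fuzzy_threshold: float = 0.9,
) -> pd.DataFrame:
    rows = []
    for raw in names:
        r = resolve_taxon(raw, reference, fuzzy_threshold)
        rows.append(
            {
                "raw_name": r.raw_name,
                "taxon_id": r.taxon_id,
                "method": r.method,
                "genus": r.genus,
                "similarity": round(r.similarity, 4),
                "needs_review": r.needs_review,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "raw_name", "taxon_id", "method", "genus", "similarity",
            "needs_review",
        ],
    )


def load_taxonomy(path: str | Path) -> list[TaxonRecord]:
    """Read a reference taxonomy CSV: taxon_id, canonical_name, rank,
    parent_genus_id (blank for genera)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        parent = getattr(row, "parent_genus_id", None)
        parent = None if pd.isna(parent) else int(parent)
        records.append(
            TaxonRecord(int(row.taxon_id), str(row.canonical_name),
                        str(row.rank), parent)
        )
    ids = [r.taxon_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate taxon_id in reference taxonomy")
    return records


# Clade assignments for genera discussed in connection with the 12 primary
# Lamiaceae clades (Li et al. chloroplast-phylogeny backbone).  Users supply
# fuller maps as CSV; this fixture covers the genera named in this package's
# documentation and examples.
DEFAULT_CLADE_ROWS: list[tuple[str, str]] = [
    ("Salvia", "Nepetoideae"),
    ("Mentha", "Nepetoideae"),
    ("Origanum", "Nepetoideae"),
    ("Nepeta", "Nepetoideae"),
    ("Perovskia", "Nepetoideae"),
    ("Hyptis", "Nepetoideae"),
    ("Isodon", "Nepetoideae"),
    ("Plectranthus", "Nepetoideae"),
    ("Ajuga", "Ajugoideae"),
    ("Teucrium", "Ajugoideae"),
    ("Clerodendrum", "Ajugoideae"),
    ("Marrubium", "Lamioideae"),
    ("Leonotis", "Lamioideae"),
    ("Pogostemon", "Lamioideae"),
    ("Leonurus", "Lamioideae"),
    ("Vitex", "Viticoideae"),
    ("Tectona", "Tectonoideae"),
    ("Premna", "Premnoideae"),
    ("Prostanthera", "Prostantheroideae"),
    ("Callicarpa", "Callicarpoideae"),
    ("Scutellaria", "Scutellarioideae"),
    ("Symphorema", "Symphorematoideae"),
    ("Peronema", "Peronematoideae"),
    ("Cymaria", "Cymarioideae"),
]


def default_clade_map() -> CladeMap:
    return CladeMap(DEFAULT_CLADE_ROWS)
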