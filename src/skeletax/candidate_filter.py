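"""Homology-hit filtering and identity-threshold peptide merging.

Candidate enzyme selection from transcriptome assemblies works on standard
tabular homology-search output (12-column outfmt-6 dialect).  For every
subject sequence, the "most similar query" is its highest-bitscore hit; a
subject survives iff that hit shows at least 35% identity and at least 70%
query coverage (boundary inclusive — the rule removes strictly-below
values).  Near-identical peptides (>= 95% global identity) are merged by
greedy length-descending clustering, the convention of CD-HIT-style tools.

Pairwise identity is computed from a global affine-gap alignment (default
match +1, mismatch -1, gap open -5, gap extend -1) as identical aligned
columns over the length of the shorter sequence.  Among co-optimal
alignments the one with the most identical columns is used, which makes
the reported identity deterministic and well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bitscore",
]


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    query_length: int

    def validate(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(
                f"identity {self.percent_identity} outside [0,100]"
            )
        if not (1 <= self.q_start <= self.q_end <= self.query_length):
            raise ValueError(
                f"bad query coordinates {self.q_start}..{self.q_end} "
                f"(length {self.query_length})"
            )


@dataclass
class FilterConfig:
    min_identity: float = 35.0
    min_coverage: float = 70.0
    coverage_basis: str = "best_hsp"  # or "merged_hsps"

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_coverage):
            if not (0.0 <= v <= 100.0):
                raise ValueError("thresholds must be in [0,100]")
        if self.coverage_basis not in ("best_hsp", "merged_hsps"):
            raise ValueError(f"unknown coverage basis {self.coverage_basis!r}")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def parse_hit_table(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[HomologyHit]:
    """Parse a 12-column tab-separated hit table, joining query lengths.

    Malformed rows and unknown query ids raise with the offending line
    number.
    """
    hits = []
    for lineno, raw in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            hit = HomologyHit(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                alignment_length=int(fields[3]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                query_length=_query_length(fields[0], query_lengths, lineno),
            )
            hit.validate()
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def _query_length(
    qid: str, lengths: Mapping[str, int], lineno: int
) -> int:
    if qid not in lengths:
        raise ValueError(f"line {lineno}: no length known for query {qid!r}")
    return int(lengths[qid])


# ---------------------------------------------------------------------------
# Coverage and filtering
# ---------------------------------------------------------------------------

def query_coverage(
    hits: HomologyHit | Sequence[HomologyHit], basis: str = "best_hsp"
) -> float:
    """Percent of the query spanned by the alignment(s).

    ``best_hsp``: span of the single (best) HSP.  ``merged_hsps``: length
    of the union of all HSP query intervals.  With a single hit both bases
    agree.
    """
    group = [hits] if isinstance(hits, HomologyHit) else list(hits)
    if not group:
        raise ValueError("empty hit group")
    qlen = group[0].query_length
    if basis == "best_hsp":
        spans = [h.q_end - h.q_start + 1 for h in group]
        return 100.0 * max(spans) / qlen
    if basis == "merged_hsps":
        intervals = sorted((h.q_start, h.q_end) for h in group)
        covered = 0
        cur_start, cur_end = intervals[0]
        for s, e in intervals[1:]:
            if s <= cur_end + 1:
                cur_end = max(cur_end, e)
            else:
                covered += cur_end - cur_start + 1
                cur_start, cur_end = s, e
        covered += cur_end - cur_start + 1
        return 100.0 * covered / qlen
    raise ValueError(f"unknown coverage basis {basis!r}")


def filter_candidates(
    hits: Iterable[HomologyHit], config: Optional[FilterConfig] = None
) -> pd.DataFrame:
    """Apply the identity/coverage rule per subject.

    For each subject the most similar query is the hit with the highest
    bitscore (ties: higher identity, then lexicographic query_id).  The
    subject is retained iff that hit has identity >= min_identity AND its
    coverage (on the configured basis, over the HSPs of that query-subject
    pair) >= min_coverage.

    Returns one row per subject: subject_id, best_query, identity,
    coverage, retained.
    """
    cfg = config or FilterConfig()
    by_subject: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_subject.setdefault(h.subject_id, []).append(h)
    rows = []
    for subject_id in sorted(by_subject):
        group = by_subject[subject_id]
        best = min(
            group,
            key=lambda h: (-h.bitscore, -h.percent_identity, h.query_id),
        )
        pair_hsps = [h for h in group if h.query_id == best.query_id]
        if cfg.coverage_basis == "best_hsp":
            coverage = query_coverage(best, "best_hsp")
        else:
            coverage = query_coverage(pair_hsps, "merged_hsps")
        retained = (
            best.percent_identity >= cfg.min_identity
            and coverage >= cfg.min_coverage
        )
        rows.append(
            {
                "subject_id": subject_id,
                "best_query": best.query_id,
                "identity": best.percent_identity,
                "coverage": round(coverage, 4),
                "retained": retained,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "best_query", "identity", "coverage",
                 "retained"],
    )


# ---------------------------------------------------------------------------
# Pairwise identity and greedy clustering
# ---------------------------------------------------------------------------

@dataclass
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0    # charged on the first residue of a gap
    gap_extend: float = -1.0


def pairwise_identity(
    a: str, b: str, scoring: Optional[AlignmentScoring] = None
) -> float:
    """Percent identity from a global affine-gap alignment of two peptides.

    identity = 100 * identical aligned columns / len(shorter sequence);
    among all optimal-score alignments the maximal identical-column count
    is used (computed by a Gotoh dynamic program over lexicographic
    (score, matches) values, which is exact because edge increments are
    history-independent).
    """
    sc = scoring or AlignmentScoring()
    for name, s in (("a", a), ("b", b)):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        bad = set(s.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid characters in sequence {name}: {bad}")
    a, b = a.upper(), b.upper()
    _, matches = _global_align(a, b, sc)
    return 100.0 * matches / min(len(a), len(b))


NEG_INF = float("-inf")


def _global_align(
    a: str, b: str, sc: AlignmentScoring
) -> tuple[float, int]:
    """Gotoh global alignment maximizing (score, identical columns).

    Returns the optimal score and the maximum number of identical columns
    achievable at that score.  End gaps are penalized (true global mode).
    """
    n, m = len(a), len(b)
    gap1 = sc.gap_open + sc.gap_extend  # opening a gap of length 1
    bad = (NEG_INF, 0)
    # states: M (a[i] aligned to b[j]), X (gap in b), Y (gap in a)
    prev_m = [bad] * (m + 1)
    prev_x = [bad] * (m + 1)
    prev_y = [bad] * (m + 1)
    prev_m[0] = (0.0, 0)
    for j in range(1, m + 1):
        prev_y[j] = (gap1 + sc.gap_extend * (j - 1), 0)
    for i in range(1, n + 1):
        cur_m = [bad] * (m + 1)
        cur_x = [bad] * (m + 1)
        cur_y = [bad] * (m + 1)
        cur_x[0] = (gap1 + sc.gap_extend * (i - 1), 0)
        for j in range(1, m + 1):
            sub = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            is_match = 1 if a[i - 1] == b[j - 1] else 0
            best_prev = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1])
            if best_prev[0] > NEG_INF:
                cur_m[j] = (best_prev[0] + sub, best_prev[1] + is_match)
            # gap in b (consume a[i-1])
            open_x = prev_m[j]
            ext_x = prev_x[j]
            cand_x = max(
                (open_x[0] + gap1, open_x[1]),
                (ext_x[0] + sc.gap_extend, ext_x[1]),
                (prev_y[j][0] + gap1, prev_y[j][1]),
            )
            if cand_x[0] > NEG_INF:
                cur_x[j] = cand_x
            # gap in a (consume b[j-1])
            cand_y = max(
                (cur_m[j - 1][0] + gap1, cur_m[j - 1][1]),
                (cur_y[j - 1][0] + sc.gap_extend, cur_y[j - 1][1]),
                (cur_x[j - 1][0] + gap1, cur_x[j - 1][1]),
            )
            if cand_y[0] > NEG_INF:
                cur_y[j] = cand_y
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return max(prev_m[m], prev_x[m], prev_y[m])


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]  # includes the representative


def greedy_cluster(
    sequences: Mapping[str, str],
    threshold: float = 95.0,
    scoring: Optional[AlignmentScoring] = None,
) -> list[Cluster]:
    """Greedy length-descending clustering at an identity threshold.

    Sequences are visited longest first (ties: lexicographic id); each
    joins the FIRST existing representative with identity >= threshold,
    else founds a new cluster.  Deterministic for a given input.
    """
    ids = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    if len(ids) != len(set(ids)):
        raise ValueError("sequence ids must be unique")
    clusters: list[Cluster] = []
    for sid in ids:
        seq = sequences[sid]
        for cluster in clusters:
            rep = sequences[cluster.representative_id]
            if pairwise_identity(seq, rep, scoring) >= threshold:
                cluster.member_ids.append(sid)
                break
        else:
            clusters.append(Cluster(sid, [sid]))
    return clusters


def clusters_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "representative_id": c.representative_id,
                "n_members": len(c.member_ids),
                "member_ids": ";".join(c.member_ids),
            }
            for c in clusters
        ],
        columns=["representative_id", "n_members", "member_ids"],
    )
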