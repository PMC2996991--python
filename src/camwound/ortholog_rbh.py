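"""EST-to-mRNA assignment by ranked alignment hits and reciprocal-best-hit orthology.

The chicken array probes were designed mostly from ESTs, so each EST query is
first assigned a full-length mRNA via its best acceptable alignment hit; hits
are classified Good / Reasonable / Bad from alignment length and percent
identity, and Bad hits are discarded.  Chicken-human ortholog pairs are then
predicted by the reciprocal-best-hit (RBH) rule on bidirectional hit tables.
Alignment execution is out of scope: this module consumes standard BLAST
tabular (outfmt 6) files.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


class HitRank(Enum):
    GOOD = "Good"
    REASONABLE = "Reasonable"
    BAD = "Bad"


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise alignment record (BLAST-style)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bit_score: float
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent identity must lie in [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.e_value < 0:
            raise ValueError("e-value must be non-negative")


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit ortholog pair with its two supporting hits."""

    species_a_id: str
    species_b_id: str
    forward_hit: AlignmentHit
    reverse_hit: AlignmentHit


def rank_hit(h: AlignmentHit) -> HitRank:
    """Classify a hit as Good, Reasonable or Bad.

    Good: alignment length > 100 and identity >= 96%.  Reasonable: length >
    100 and 90% < identity <= 95%.  Bad: everything else — including, by the
    literal "all other hits" clause, identities strictly between 95 and 96.
    """
    if h.alignment_length > 100 and h.percent_identity >= 96:
        return HitRank.GOOD
    if h.alignment_length > 100 and 90 < h.percent_identity <= 95:
        return HitRank.REASONABLE
    return HitRank.BAD


def read_blast_tabular(path) -> list[AlignmentHit]:
    """Parse a BLAST outfmt-6 tabular file into :class:`AlignmentHit` records."""
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    return [
        AlignmentHit(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            percent_identity=float(r.pident),
            alignment_length=int(r.length),
            bit_score=float(r.bitscore),
            e_value=float(r.evalue),
        )
        for r in df.itertuples()
    ]


def write_blast_tabular(hits: list[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            aln = h.alignment_length
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        aln,
                        max(0, round(aln * (100 - h.percent_identity) / 100)),
                        0,
                        1,
                        aln,
                        1,
                        aln,
                        f"{h.e_value:.2g}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


def _hit_sort_key(h: AlignmentHit):
    # best first: highest bit score, then identity, then longest alignment,
    # then lexicographically smallest subject id (deterministic total order)
    return (-h.bit_score, -h.percent_identity, -h.alignment_length, h.subject_id)


def best_hit(hits: list[AlignmentHit]) -> AlignmentHit | None:
    """Deterministic best hit under the bit-score / identity / subject-id order."""
    if not hits:
        return None
    return min(hits, key=_hit_sort_key)


def assign_full_length(est_hits: list[AlignmentHit]) -> dict[str, str | None]:
    """Assign each EST query its best Good/Reasonable full-length subject.

    Bad hits are discarded; among survivors the highest bit score wins (ties:
    higher identity, then longer alignment, then smallest subject id).
    Queries with no surviving hit map to ``None``.
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in est_hits:
        by_query.setdefault(h.query_id, []).append(h)
    assignment: dict[str, str | None] = {}
    for query, hits in by_query.items():
        surviving = [h for h in hits if rank_hit(h) is not HitRank.BAD]
        chosen = best_hit(surviving)
        assignment[query] = chosen.subject_id if chosen else None
    return assignment


def reciprocal_best_hits(
    a_to_b: list[AlignmentHit], b_to_a: list[AlignmentHit]
) -> list[OrthologPair]:
    """One-to-one ortholog pairs by the reciprocal-best-hit rule.

    ``(a, b)`` is reported iff ``b`` is ``a``'s best hit in the forward table
    and ``a`` is ``b``'s best hit in the reverse table, with the deterministic
    tie-break order of :func:`best_hit`.  Output is sorted by the species-A
    identifier and is a one-to-one partial matching by construction.
    """
    fwd_by_query: dict[str, list[AlignmentHit]] = {}
    for h in a_to_b:
        fwd_by_query.setdefault(h.query_id, []).append(h)
    rev_by_query: dict[str, list[AlignmentHit]] = {}
    for h in b_to_a:
        rev_by_query.setdefault(h.query_id, []).append(h)

    best_fwd = {q: best_hit(hits) for q, hits in fwd_by_query.items()}
    best_rev = {q: best_hit(hits) for q, hits in rev_by_query.items()}

    pairs = []
    for a, fh in best_fwd.items():
        if fh is None:
            continue
        b = fh.subject_id
        rh = best_rev.get(b)
        if rh is not None and rh.subject_id == a:
            pairs.append(OrthologPair(a, b, fh, rh))
    return sorted(pairs, key=lambda p: p.species_a_id)


def ortholog_map(pairs: list[OrthologPair]) -> dict[str, str]:
    """Species-A id -> species-B id mapping from RBH pairs."""
    return {p.species_a_id: p.species_b_id for p in pairs}


def pairs_table(pairs: list[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_a_id": [p.species_a_id for p in pairs],
            "species_b_id": [p.species_b_id for p in pairs],
            "forward_bit_score": [p.forward_hit.bit_score for p in pairs],
            "forward_identity": [p.forward_hit.percent_identity for p in pairs],
            "reverse_bit_score": [p.reverse_hit.bit_score for p in pairs],
            "reverse_identity": [p.reverse_hit.percent_identity for p in pairs],
        }
    )


def write_pairs_table(pairs: list[OrthologPair], path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pairs_table(pairs).to_csv(fh, sep="\t", index=False)
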