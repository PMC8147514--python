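"""Local pairwise alignment engines for the extension stage.

Seeds found by the domain search are extended against a reference set of
known IS elements (nucleotide level) and transposase ORFs (protein level).
Three engines serve that stage: protein Smith-Waterman (BLOSUM62, affine
gaps), nucleotide Smith-Waterman on both strands, and a translated search
aligning all six frames of a genomic window against a protein database.

All engines run an O(min-memory) affine DP to locate the best local
alignment, then a full traceback on the clipped footprint to count
identities. Gap convention: a gap of length k costs open + k * extend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from ._kernels import sw_score, sw_trace
from .genome import GenomicInterval, aa_to_genomic, six_frame_translate

__all__ = [
    "AlignmentHit",
    "local_align_protein",
    "local_align_dna",
    "translated_search",
    "hit_order_key",
]

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
DNA_ALPHABET = "ACGT"

# BLAST-like defaults; the sources fix none of these, so they are exposed.
PROT_GAP_OPEN = 11.0
PROT_GAP_EXTEND = 1.0
DNA_MATCH = 2.0
DNA_MISMATCH = -3.0
DNA_GAP_OPEN = 5.0
DNA_GAP_EXTEND = 2.0


def _blosum62_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    K = len(PROTEIN_ALPHABET)
    sub = np.zeros((K + 1, K + 1))
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            sub[i, j] = blosum[a, b]
    sub[K, :] = sub[:, K] = -4.0  # any residue outside the alphabet
    return sub


def _dna_matrix(match: float, mismatch: float) -> np.ndarray:
    sub = np.full((5, 5), mismatch)
    np.fill_diagonal(sub, match)
    sub[4, :] = sub[:, 4] = mismatch  # N and friends never match
    return sub


_BLOSUM62 = _blosum62_matrix()
_PROT_CODES = np.full(128, len(PROTEIN_ALPHABET), np.int64)
for _i, _c in enumerate(PROTEIN_ALPHABET):
    _PROT_CODES[ord(_c)] = _i
_DNA_CODES = np.full(128, 4, np.int64)
for _i, _c in enumerate(DNA_ALPHABET):
    _DNA_CODES[ord(_c)] = _i


def _encode(seq: str, codes: np.ndarray) -> np.ndarray:
    return codes[np.frombuffer(seq.upper().encode("ascii"), np.uint8).astype(np.int64)]


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a query region against one database item."""

    db_id: str
    query_span: GenomicInterval
    db_start: int
    db_end: int
    score: float
    identities: int
    aligned_len: int

    def __post_init__(self) -> None:
        if self.identities > self.aligned_len:
            raise ValueError("identities cannot exceed alignment length")


def hit_order_key(hit: AlignmentHit):
    """Total ordering for "best hit" selection: higher score, then more
    identities, then longer alignment, then lexicographic db id."""
    return (-hit.score, -hit.identities, -hit.aligned_len, hit.db_id)


def _align(q: np.ndarray, d: np.ndarray, sub: np.ndarray, go: float, ge: float):
    """Score pass then traceback on the clipped footprint. Returns
    (score, identities, aligned_len, qs, qe, ds, de) or None."""
    score, qs, qe, ds, de = sw_score(q, d, sub, go, ge)
    if score <= 0.0 or qe <= qs or de <= ds:
        return None
    s2, ident, alen, rqs, rqe, rds, rde = sw_trace(q[qs:qe], d[ds:de], sub, go, ge)
    return (
        float(s2),
        int(ident),
        int(alen),
        qs + rqs,
        qs + rqe,
        ds + rds,
        ds + rde,
    )


def local_align_protein(
    query: str,
    db_item: str,
    db_id: str = "db",
    query_offset: int = 0,
    seq_id: str = "query",
    gap_open: float = PROT_GAP_OPEN,
    gap_extend: float = PROT_GAP_EXTEND,
    sub_matrix: np.ndarray | None = None,
) -> AlignmentHit | None:
    """Best Smith-Waterman local alignment of two protein sequences
    (default BLOSUM62, gap open 11 / extend 1), or None when no positive-
    scoring alignment exists. The query span is reported in amino-acid
    offsets (shifted by ``query_offset``)."""
    if not query or not db_item:
        return None
    res = _align(
        _encode(query, _PROT_CODES),
        _encode(db_item, _PROT_CODES),
        sub_matrix if sub_matrix is not None else _BLOSUM62,
        gap_open,
        gap_extend,
    )
    if res is None:
        return None
    score, ident, alen, qs, qe, ds, de = res
    return AlignmentHit(
        db_id,
        GenomicInterval(seq_id, query_offset + qs, query_offset + qe, "+"),
        ds,
        de,
        score,
        ident,
        alen,
    )


def local_align_dna(
    query: str,
    db_item: str,
    db_id: str = "db",
    query_offset: int = 0,
    seq_id: str = "query",
    match: float = DNA_MATCH,
    mismatch: float = DNA_MISMATCH,
    gap_open: float = DNA_GAP_OPEN,
    gap_extend: float = DNA_GAP_EXTEND,
) -> AlignmentHit | None:
    """Best nucleotide Smith-Waterman alignment, both strands of the query
    searched and the better retained (reverse-complement matches carry
    strand '-'). Query span is always on forward coordinates."""
    if not query or not db_item:
        return None
    from .genome import reverse_complement

    sub = _dna_matrix(match, mismatch)
    d = _encode(db_item, _DNA_CODES)
    n = len(query)
    best = None
    for strand in ("+", "-"):
        qseq = query if strand == "+" else reverse_complement(query)
        res = _align(_encode(qseq, _DNA_CODES), d, sub, gap_open, gap_extend)
        if res is None:
            continue
        score, ident, alen, qs, qe, ds, de = res
        if strand == "-":
            qs, qe = n - qe, n - qs
        hit = AlignmentHit(
            db_id,
            GenomicInterval(seq_id, query_offset + qs, query_offset + qe, strand),
            ds,
            de,
            score,
            ident,
            alen,
        )
        if best is None or hit_order_key(hit) < hit_order_key(best):
            best = hit
    return best


def translated_search(
    window_seq: str,
    window_start: int,
    seq_id: str,
    protein_db,
    gap_open: float = PROT_GAP_OPEN,
    gap_extend: float = PROT_GAP_EXTEND,
) -> list[AlignmentHit]:
    """Align all six reading frames of a genomic window against each
    protein in the database; the best frame per database item wins.

    Query spans are projected back to forward-strand genomic nucleotide
    coordinates (multiples of 3 nt), shifted by ``window_start``.
    Identities are counted on amino acids.
    """
    hits: list[AlignmentHit] = []
    L = len(window_seq)
    frames = six_frame_translate(seq_id, window_seq)
    for rec in protein_db:
        best = None
        for ft in frames:
            if not ft.aa_seq:
                continue
            aa_hit = local_align_protein(
                ft.aa_seq, rec.seq, rec.id, 0, seq_id, gap_open, gap_extend
            )
            if aa_hit is None:
                continue
            giv = aa_to_genomic(
                seq_id, ft.frame, aa_hit.query_span.start, aa_hit.query_span.end, L
            )
            hit = AlignmentHit(
                rec.id,
                GenomicInterval(
                    seq_id, window_start + giv.start, window_start + giv.end, giv.strand
                ),
                aa_hit.db_start,
                aa_hit.db_end,
                aa_hit.score,
                aa_hit.identities,
                aa_hit.aligned_len,
            )
            if best is None or hit_order_key(hit) < hit_order_key(best):
                best = hit
        if best is not None:
            hits.append(best)
    hits.sort(key=hit_order_key)
    return hits
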