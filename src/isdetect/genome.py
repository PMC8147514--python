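"""Strand/frame algebra for prokaryotic contigs.

Six-frame translation of whole sequences (not just ORFs) and the mapping
between amino-acid coordinates on a reading frame and nucleotide intervals
on the forward genomic sequence. All internal coordinates are 0-based,
half-open; conversion to 1-based inclusive happens only at format
boundaries (GenBank/GFF3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable

__all__ = [
    "GenomicInterval",
    "FrameTranslation",
    "six_frame_translate",
    "aa_to_genomic",
    "overlap_len",
    "gap_distance",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

#: frames are labelled +1,+2,+3 (forward strand, codon offsets 0,1,2) and
#: -1,-2,-3 (reverse complement, codon offsets 0,1,2 on the rc sequence)
FRAMES = (1, 2, 3, -1, -2, -3)


def _codon_map(table_id: int = 11) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codons = dict(table.forward_table)
    for stop in table.stop_codons:
        codons[stop] = "*"
    return codons


_TABLE11 = _codon_map(11)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FrameTranslation:
    """Conceptual translation of one reading frame of a contig."""

    seq_id: str
    frame: int
    aa_seq: str
    frame_offset: int = field(default=0)

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}, got {self.frame}")


def _translate(nt: str, table: dict[str, str] | None = None) -> str:
    """Translate in frame 0. Any codon containing a non-ACGT symbol emits 'X';
    stop codons emit '*'."""
    table = table or _TABLE11
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append(table.get(codon, "X"))
    return "".join(out)


def six_frame_translate(
    seq_id: str, seq: str, table_id: int = 11
) -> list[FrameTranslation]:
    """Translate a nucleotide sequence in all six frames.

    The whole sequence is translated, not only open reading frames, so
    catalytic domains interrupted by frameshifts or lying in unannotated
    regions are still visible to the domain search. Uses the
    bacterial/archaeal genetic code (translation table 11) by default.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) < 3:
        warnings.warn(f"{seq_id}: sequence shorter than one codon, empty translations")
        return [FrameTranslation(seq_id, f, "", abs(f) - 1) for f in FRAMES]
    table = _codon_map(table_id) if table_id != 11 else _TABLE11
    rc = reverse_complement(seq)
    out = []
    for frame in FRAMES:
        off = abs(frame) - 1
        src = seq if frame > 0 else rc
        out.append(FrameTranslation(seq_id, frame, _translate(src[off:], table), off))
    return out


def aa_to_genomic(
    seq_id: str, frame: int, aa_start: int, aa_end: int, seq_len: int
) -> GenomicInterval:
    """Map an amino-acid span on a reading frame back to the forward-strand
    nucleotide interval of its codons.

    For reverse frames the span is read on the reverse complement and
    reflected onto forward coordinates; the resulting interval carries
    strand '-'.
    """
    off = abs(frame) - 1
    n_aa = (seq_len - off) // 3
    if not (0 <= aa_start < aa_end <= n_aa):
        raise ValueError(
            f"aa span [{aa_start}, {aa_end}) outside frame {frame} "
            f"of length {n_aa} (seq_len={seq_len})"
        )
    lo = off + 3 * aa_start
    hi = off + 3 * aa_end
    if frame > 0:
        return GenomicInterval(seq_id, lo, hi, "+")
    return GenomicInterval(seq_id, seq_len - hi, seq_len - lo, "-")


def overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    """Nucleotides shared by two intervals; 0 across different sequences.
    Strand-agnostic: overlap tests in classification and evaluation ignore
    strand."""
    if a.seq_id != b.seq_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in nt between two intervals on one sequence; 0 if they overlap
    or are adjacent."""
    if a.seq_id != b.seq_id:
        raise ValueError("gap_distance requires intervals on the same sequence")
    return max(0, max(a.start, b.start) - min(a.end, b.end))
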