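"""Reading and writing the standard formats the pipeline touches.

FASTA in (contigs and reference databases), GenBank flat files in
(optional annotation used for hit classification), GFF3/CSV/summary text
out. Sequence parsing is delegated to Biopython; this module enforces the
package's conventions: upper-case residues, U normalised to T, 0-based
half-open internal coordinates with conversion only at format boundaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

from .genome import GenomicInterval

__all__ = [
    "SeqRecord",
    "AnnotationFeature",
    "read_fasta",
    "read_genbank_features",
    "write_gff3",
    "read_gff3",
    "write_csv",
    "write_summary",
]

_NT_CHARS = set("ACGTRYSWKMBDHVN")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWY" + "X*")


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence, nucleotide or amino acid."""

    id: str
    seq: str
    moltype: str  # "nt" | "aa"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        if self.moltype not in ("nt", "aa"):
            raise ValueError(f"moltype must be 'nt' or 'aa', got {self.moltype!r}")
        allowed = _NT_CHARS if self.moltype == "nt" else _AA_CHARS
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(f"{self.id}: illegal {self.moltype} characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AnnotationFeature:
    """One span of a GenBank feature. Compound (join/complement) locations
    are flattened to one AnnotationFeature per span, all sharing the parent
    record's qualifiers."""

    ftype: str
    interval: GenomicInterval
    qualifiers: dict = field(default_factory=dict)
    pseudo_incomplete: bool = False


def read_fasta(path, moltype: str = "nt") -> list[SeqRecord]:
    """Read a FASTA file into a list of records, order preserved.

    Whitespace within sequences is stripped, residues are upper-cased and
    U is normalised to T for nucleotide input.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if moltype == "nt":
            seq = seq.replace("U", "T")
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SeqRecord(rec.id, seq, moltype))
    return records


def _is_pseudo_incomplete(qualifiers: dict) -> bool:
    if "pseudo" not in qualifiers and "pseudogene" not in qualifiers:
        return False
    text = " ".join(
        v for k, vals in qualifiers.items() if k != "translation" for v in vals
    ).lower()
    return "incomplete" in text


def read_genbank_features(path) -> dict[str, list[AnnotationFeature]]:
    """Parse the FEATURES table of a GenBank flat file.

    Returns a map from record id to features with 0-based half-open
    intervals. Fragments newly marked ``/pseudo`` with an ``incomplete``
    note are flagged ``pseudo_incomplete`` so classification can ignore
    them. Unparsable locations are skipped with a warning.
    """
    out: dict[str, list[AnnotationFeature]] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        feats: list[AnnotationFeature] = []
        for f in rec.features:
            if f.type == "source":
                continue
            quals = {k: list(v) if isinstance(v, (list, tuple)) else [str(v)]
                     for k, v in f.qualifiers.items()}
            pseudo = _is_pseudo_incomplete(quals)
            try:
                parts = f.location.parts
            except AttributeError:
                warnings.warn(f"{rec.id}: skipping feature with unparsable location")
                continue
            for part in parts:
                start, end = int(part.start), int(part.end)
                if end <= start:
                    warnings.warn(f"{rec.id}: skipping zero-length span in {f.type}")
                    continue
                strand = "-" if part.strand == -1 else "+"
                feats.append(
                    AnnotationFeature(
                        ftype=f.type,
                        interval=GenomicInterval(rec.id, start, end, strand),
                        qualifiers=quals,
                        pseudo_incomplete=pseudo,
                    )
                )
        out[rec.id] = feats
    return out


def _gff3_escape(text: str) -> str:
    return re.sub(r"[;=&,\t\n%]", lambda m: "%%%02X" % ord(m.group()), str(text))


def write_gff3(hits, path) -> None:
    """Write classified hits as GFF3 (1-based inclusive coordinates).

    The score column carries the seed bit score; attributes carry the
    reporting level, SeqID percentages, similarity/GenBank classes and the
    contributing model names.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits, start=1):
            iv = h.interval
            attrs = [
                ("ID", f"is{i}"),
                ("level", h.level),
                ("seqid_dna", f"{h.seqid_dna:.2f}"),
                ("seqid_orf", f"{h.seqid_orf:.2f}"),
                ("sim_dna", h.sim_dna),
                ("sim_orf", h.sim_orf),
                ("genbank_class", h.genbank_class),
                ("models", ",".join(_gff3_escape(m) for m in h.models)),
            ]
            if h.best_is_id:
                attrs.append(("best_is", h.best_is_id))
            if h.best_orf_id:
                attrs.append(("best_orf", h.best_orf_id))
            attr_s = ";".join(
                f"{k}={v if k == 'models' else _gff3_escape(v)}" for k, v in attrs
            )
            fh.write(
                "\t".join(
                    [
                        iv.seq_id,
                        "isdetect",
                        "mobile_element",
                        str(iv.start + 1),
                        str(iv.end),
                        f"{h.bit_score:.1f}",
                        iv.strand,
                        ".",
                        attr_s,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[tuple[GenomicInterval, float, dict]]:
    """Parse a GFF3 file written by :func:`write_gff3` (or any simple GFF3)
    back into (interval, score, attributes) triples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _, _, start, end, score, strand, _, attrs = line.rstrip("\n").split("\t")
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k] = re.sub(
                        "%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), v
                    )
            out.append(
                (
                    GenomicInterval(seqid, int(start) - 1, int(end), strand),
                    float(score),
                    attr_map,
                )
            )
    return out


CSV_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "strand",
    "level",
    "bit_score",
    "evalue",
    "seqid_orf",
    "seqid_dna",
    "best_orf",
    "best_is",
    "models",
    "genbank_class",
]


def write_csv(hits, path) -> None:
    """Write one row per classified hit. Coordinates are 1-based inclusive
    as in the GFF3 output; SeqID percentages are formatted to 2 decimals."""
    with open(path, "w") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for h in hits:
            iv = h.interval
            row = [
                iv.seq_id,
                str(iv.start + 1),
                str(iv.end),
                iv.strand,
                h.level,
                f"{h.bit_score:.1f}",
                f"{h.evalue:.3g}",
                f"{h.seqid_orf:.2f}",
                f"{h.seqid_dna:.2f}",
                h.best_orf_id or "NA",
                h.best_is_id or "NA",
                ";".join(h.models),
                h.genbank_class,
            ]
            fh.write(",".join(row) + "\n")


def write_summary(hits, genome_lengths: dict[str, int], path) -> None:
    """Per-family hit counts plus the total bp covered by hits (union of
    intervals) and the fraction of the input they occupy."""
    family_counts: dict[str, int] = {}
    by_seq: dict[str, list[tuple[int, int]]] = {}
    n_hits = 0
    for h in hits:
        n_hits += 1
        fam = h.models[0] if h.models else "unknown"
        family_counts[fam] = family_counts.get(fam, 0) + 1
        by_seq.setdefault(h.interval.seq_id, []).append(
            (h.interval.start, h.interval.end)
        )
    covered = 0
    for spans in by_seq.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    total = sum(genome_lengths.values())
    pct = 100.0 * covered / total if total else 0.0
    with open(path, "w") as fh:
        fh.write("family\tcount\n")
        for fam in sorted(family_counts):
            fh.write(f"{fam}\t{family_counts[fam]}\n")
        fh.write(f"total_hits\t{n_hits}\n")
        fh.write(f"bp_covered\t{covered}\n")
        fh.write(f"pct_of_input\t{pct:.1f}\n")
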