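"""Hit classification: sequence-similarity categories and GenBank categories.

Two orthogonal labels help the user judge each reported element. The
similarity label compares the hit's SeqID against per-level thresholds
(DNA level 50/70 %, ORF level 25/45 %): *intra* — similarity typical of
members of one IS family; *inter* — similarity common between members of
different families; *improbable* — lower than usual among family members.

The GenBank label, available when an annotation file was provided, places
each hit into exactly one of three categories by rule order: *IS-related*
(overlaps a mobile-element record, an IS-keyword-annotated feature, or an
integrase record when the hit also shows non-improbable similarity),
*no-annotation* (no overlapping feature, or only uninformative products
such as hypothetical proteins), and *other-annotation* otherwise.
Annotation fragments marked pseudo/incomplete are ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GenomicInterval, overlap_len
from .pipeline import ExtendedHit, PipelineConfig
from .seqio import AnnotationFeature

__all__ = [
    "Table1Thresholds",
    "ClassifiedHit",
    "IS_KEYWORDS",
    "UNINFORMATIVE_PRODUCTS",
    "similarity_category",
    "genbank_category",
    "classify_hits",
]


@dataclass(frozen=True)
class Table1Thresholds:
    """Similarity-category boundaries (percent identity over the database
    item's full length)."""

    dna_low: float = 50.0
    dna_high: float = 70.0
    orf_low: float = 25.0
    orf_high: float = 45.0

    def __post_init__(self) -> None:
        if not (self.dna_low < self.dna_high and self.orf_low < self.orf_high):
            raise ValueError("low threshold must be below high threshold")


#: keywords whose presence in an overlapping feature's text marks a hit
#: IS-related; matching is case-insensitive substring search
IS_KEYWORDS = (
    "transposase",
    "resolvase",
    "recombinase",
    "recombination/resolution",
    "insertion element",
    "insertion sequence",
    "mobile element",
    "transposon",
    "transposable element",
    "dde",
)

#: products that leave a hit effectively unannotated
UNINFORMATIVE_PRODUCTS = (
    "hypothetical protein",
    "predicted protein",
    "unknown",
    "duf",
    "domain of unknown function",
)

_TEXT_QUALIFIERS = ("product", "note", "function", "gene", "mobile_element_type")


@dataclass(frozen=True)
class ClassifiedHit:
    """An extended hit plus its similarity and GenBank categories."""

    hit: ExtendedHit
    sim_dna: str
    sim_orf: str
    genbank_class: str  # IS-related | no-annotation | other-annotation | NA

    # writer-facing delegation
    @property
    def interval(self) -> GenomicInterval:
        return self.hit.interval

    @property
    def level(self) -> str:
        return self.hit.level

    @property
    def bit_score(self) -> float:
        return self.hit.bit_score

    @property
    def evalue(self) -> float:
        return self.hit.evalue

    @property
    def models(self):
        return self.hit.models

    @property
    def seqid_dna(self) -> float:
        return self.hit.seqid_dna

    @property
    def seqid_orf(self) -> float:
        return self.hit.seqid_orf

    @property
    def best_is_id(self):
        return self.hit.best_is_id

    @property
    def best_orf_id(self):
        return self.hit.best_orf_id


def similarity_category(
    seqid: float, level: str, th: Table1Thresholds = Table1Thresholds()
) -> str:
    """intra above the high threshold (exclusive), inter between low
    (exclusive) and high (inclusive), improbable at or below low."""
    if not 0.0 <= seqid <= 100.0:
        raise ValueError("SeqID must be a percentage in [0, 100]")
    low, high = (
        (th.dna_low, th.dna_high) if level == "dna" else (th.orf_low, th.orf_high)
    )
    if seqid > high:
        return "intra"
    if seqid > low:
        return "inter"
    return "improbable"


def _feature_text(f: AnnotationFeature) -> str:
    parts = [f.ftype]
    for q in _TEXT_QUALIFIERS:
        parts.extend(f.qualifiers.get(q, ()))
    return " ".join(parts).lower()


def genbank_category(
    hit_interval: GenomicInterval,
    features: list[AnnotationFeature],
    sim_dna: str = "improbable",
    sim_orf: str = "improbable",
    keywords=IS_KEYWORDS,
    uninformative=UNINFORMATIVE_PRODUCTS,
    family_names=(),
) -> str:
    """Classify one hit against the annotation of its contig.

    Overlap means >= 1 shared nt; pseudo/incomplete records are ignored.
    Rule order: IS-related beats no-annotation beats other-annotation.
    An overlapping integrase record counts as IS-related only when the
    hit has non-improbable similarity at either level (misannotated
    transposases are commonly labelled integrase).
    """
    import re

    overlapping = [
        f
        for f in features
        if not f.pseudo_incomplete and overlap_len(hit_interval, f.interval) >= 1
    ]
    all_keywords = tuple(k.lower() for k in keywords) + tuple(
        n.lower() for n in family_names
    )

    def kw_match(k: str, text: str) -> bool:
        # short keywords (DDE, family names like IS3) match whole words only
        if len(k) <= 4:
            return re.search(rf"\b{re.escape(k)}\b", text) is not None
        return k in text
    significant = sim_dna != "improbable" or sim_orf != "improbable"
    informative = 0
    for f in overlapping:
        text = _feature_text(f)
        if f.ftype in ("mobile_element", "mobile_element_type"):
            return "IS-related"
        if f.ftype in ("repeat_region", "CDS", "gene", "misc_feature"):
            if any(kw_match(k, text) for k in all_keywords):
                return "IS-related"
            if "integrase" in text and significant:
                return "IS-related"
        if not any(u in text for u in uninformative):
            informative += 1
    if informative == 0:
        return "no-annotation"
    return "other-annotation"


def classify_hits(
    hits: list[ExtendedHit],
    features: dict[str, list[AnnotationFeature]] | None = None,
    cfg: PipelineConfig | None = None,
    th: Table1Thresholds | None = None,
    keywords=IS_KEYWORDS,
    family_names=(),
) -> list[ClassifiedHit]:
    """Attach similarity categories (both levels) and the GenBank category
    to every hit. Without an annotation input the GenBank category is
    "NA"; similarity categories are always set."""
    if th is None:
        th = (
            Table1Thresholds(cfg.dna_low, cfg.dna_high, cfg.orf_low, cfg.orf_high)
            if cfg is not None
            else Table1Thresholds()
        )
    out = []
    for h in hits:
        sim_dna = similarity_category(h.seqid_dna, "dna", th)
        sim_orf = similarity_category(h.seqid_orf, "orf", th)
        if features is None:
            gb = "NA"
        else:
            gb = genbank_category(
                h.interval,
                features.get(h.interval.seq_id, []),
                sim_dna,
                sim_orf,
                keywords,
                family_names=family_names,
            )
        out.append(ClassifiedHit(h, sim_dna, sim_orf, gb))
    return out
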