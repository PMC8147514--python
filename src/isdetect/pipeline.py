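"""Seed-and-extend detection pipeline.

The stages mirror the workflow the package implements end to end:

1. *Seeding* — all six reading frames of every contig are scanned with the
   family profiles (domain bit score >= ``domT``) and with single-sequence
   outlier profiles (domain E-value <= ``e_dom``); every domain hit maps
   back to a genomic interval.
2. *Merging* — same-model hits on one strand within ``d_merge`` nt fuse
   (catalytic domains may carry insertions or variable segments); then
   overlapping hits from different models fuse (catalytic domains of
   different families share similarity, and a novel domain may combine
   parts of known ones).
3. *Extension* — each seed, padded with ``context_orf``/``context_dna``
   flanks, is aligned against known transposase ORFs and full IS elements;
   the best database hit that still contains the whole seed re-draws the
   boundaries, at DNA level if a known IS matched, else ORF level, else the
   seed stays at catalytic-domain level.
4. *Filtering* — hits scoring below the model's noise cutoff, hits shorter
   than ``L_min_nt``, and duplicates covering the same genomic region are
   removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .align import AlignmentHit, hit_order_key, local_align_dna, translated_search
from .genome import GenomicInterval, aa_to_genomic, gap_distance, overlap_len, six_frame_translate
from .phmm import ProfileHMM, viterbi_domain_search
from .seqio import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "Seed",
    "ExtendedHit",
    "ReferenceDB",
    "seed_scan",
    "merge_seeds",
    "extend_seed",
    "filter_hits",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Fixed parameters of the search.

    domT
        minimum domain bit score for family-profile seeds (0.0: keep any
        non-negative score).
    e_dom
        domain conditional E-value cutoff for single-sequence profiles.
    d_merge
        maximum genomic gap (nt) between same-model seeds that merge.
    context_orf, context_dna
        flank length (nt) added around a seed before matching against
        transposase ORFs and full IS elements respectively.
    L_min_nt
        hits shorter than this many nt (150 nt = 50 aa) are dropped.
    dup_overlap_frac
        two hits overlapping by at least this fraction of the shorter one
        count as duplicates of the same genomic region.
    """

    domT: float = 0.0
    e_dom: float = 0.001
    d_merge: int = 700
    context_orf: int = 1600
    context_dna: int = 14000
    L_min_nt: int = 150
    L_min_aa: int = 50
    dup_overlap_frac: float = 0.5
    dna_low: float = 50.0
    dna_high: float = 70.0
    orf_low: float = 25.0
    orf_high: float = 45.0

    def __post_init__(self) -> None:
        for name in ("domT", "e_dom", "d_merge", "context_orf", "context_dna",
                     "L_min_nt", "L_min_aa", "dup_overlap_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.context_orf > self.context_dna:
            raise ValueError("context_orf must not exceed context_dna")


@dataclass(frozen=True)
class Seed:
    """A genomic interval supported by one or more catalytic-domain hits."""

    interval: GenomicInterval
    models: tuple[str, ...]
    bit_score: float
    evalue: float
    best_model: str

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("seed without contributing models")


@dataclass(frozen=True)
class ExtendedHit:
    """A seed after database extension.

    ``level`` records which reference evidence set the boundaries: "dna"
    (a known IS element), "orf" (a known transposase), or "domain" (the
    catalytic-domain seed alone). SeqID percentages are identities of the
    best qualifying alignment normalised by the database item's full
    length, 0 when no alignment qualified at that level.
    """

    seed: Seed
    interval: GenomicInterval
    level: str
    best_is_id: str | None = None
    best_orf_id: str | None = None
    seqid_dna: float = 0.0
    seqid_orf: float = 0.0

    def __post_init__(self) -> None:
        if self.level not in ("dna", "orf", "domain"):
            raise ValueError(f"bad level {self.level!r}")
        if self.level == "dna" and not self.best_is_id:
            raise ValueError("dna-level hit without a database IS element")
        if self.level == "orf" and not self.best_orf_id:
            raise ValueError("orf-level hit without a database ORF")
        for v in (self.seqid_dna, self.seqid_orf):
            if not 0.0 <= v <= 100.0:
                raise ValueError("SeqID out of [0, 100]")

    @property
    def bit_score(self) -> float:
        return self.seed.bit_score

    @property
    def evalue(self) -> float:
        return self.seed.evalue

    @property
    def models(self) -> tuple[str, ...]:
        return self.seed.models


class ReferenceDB:
    """Reference database: known IS elements (nt) and transposase ORFs (aa).

    FASTA ids may carry ``|key=value`` tokens; ``is_id`` on an ORF links it
    to its parent IS element and ``family`` labels either kind, e.g.
    ``tp0|is_id=IS_fam1_0|family=fam1``.
    """

    def __init__(self, is_records=(), orf_records=()):
        self.is_records = list(is_records)
        self.orf_records = list(orf_records)
        self.family: dict[str, str] = {}
        self.orf_parent: dict[str, str] = {}
        self.is_len: dict[str, int] = {}
        for rec in self.is_records:
            base, tokens = self._tokens(rec.id)
            self.is_len[rec.id] = len(rec.seq)
            if "family" in tokens:
                self.family[rec.id] = tokens["family"]
        for rec in self.orf_records:
            base, tokens = self._tokens(rec.id)
            if "family" in tokens:
                self.family[rec.id] = tokens["family"]
            if "is_id" in tokens:
                parent = tokens["is_id"]
                full = next(
                    (r.id for r in self.is_records
                     if r.id == parent or r.id.split("|")[0] == parent),
                    parent,
                )
                self.orf_parent[rec.id] = full

    @staticmethod
    def _tokens(header: str) -> tuple[str, dict[str, str]]:
        parts = header.split("|")
        tokens = {}
        for p in parts[1:]:
            if "=" in p:
                k, v = p.split("=", 1)
                tokens[k] = v
        return parts[0], tokens

    @classmethod
    def from_fasta(cls, is_path=None, orf_path=None):
        from .seqio import read_fasta

        return cls(
            read_fasta(is_path, "nt") if is_path else (),
            read_fasta(orf_path, "aa") if orf_path else (),
        )


def seed_scan(
    genome: list[SeqRecord],
    models: list[ProfileHMM],
    singles: list[ProfileHMM] = (),
    cfg: PipelineConfig = PipelineConfig(),
) -> list[Seed]:
    """Scan all six frames of every contig with every profile.

    Family profiles keep domain hits with bit score >= ``cfg.domT``;
    single-sequence outlier profiles keep hits with E-value <=
    ``cfg.e_dom``. Each surviving hit becomes a one-model seed at its
    genomic codon span.
    """
    if not models and not singles:
        raise ValueError("seed_scan needs at least one profile")
    Z = 6 * len(genome)
    seeds: list[Seed] = []
    for contig in genome:
        L = len(contig.seq)
        for ft in six_frame_translate(contig.id, contig.seq):
            if not ft.aa_seq:
                continue
            for model in models:
                for h in viterbi_domain_search(
                    model, ft.aa_seq, cfg.domT, contig.id, ft.frame, Z
                ):
                    iv = aa_to_genomic(contig.id, ft.frame, h.aa_start, h.aa_end, L)
                    seeds.append(Seed(iv, (model.name,), h.bit_score, h.evalue, model.name))
            for model in singles:
                for h in viterbi_domain_search(
                    model, ft.aa_seq, 0.0, contig.id, ft.frame, Z
                ):
                    if h.evalue <= cfg.e_dom:
                        iv = aa_to_genomic(contig.id, ft.frame, h.aa_start, h.aa_end, L)
                        seeds.append(
                            Seed(iv, (model.name,), h.bit_score, h.evalue, model.name)
                        )
    seeds.sort(key=_seed_key)
    return seeds


def _seed_key(s: Seed):
    return (s.interval.seq_id, s.interval.start, s.interval.end,
            s.interval.strand, s.models)


def _fuse(a: Seed, b: Seed) -> Seed:
    iv = GenomicInterval(
        a.interval.seq_id,
        min(a.interval.start, b.interval.start),
        max(a.interval.end, b.interval.end),
        a.interval.strand,
    )
    models = a.models + tuple(m for m in b.models if m not in a.models)
    if b.bit_score > a.bit_score:
        best, score = b.best_model, b.bit_score
    else:
        best, score = a.best_model, a.bit_score
    return Seed(iv, models, score, min(a.evalue, b.evalue), best)


def merge_seeds(seeds: list[Seed], cfg: PipelineConfig = PipelineConfig()) -> list[Seed]:
    """Two merge passes, each applied transitively until fixpoint.

    Pass 1: seeds from the same model, on the same contig and strand,
    within ``d_merge`` nt of each other, fuse into their union interval
    (score = max, E-value = min). Pass 2: seeds from different models on
    the same strand that overlap by at least one nt fuse likewise, and
    their model lists concatenate.
    """

    def sweep(items: list[Seed], same_group, close) -> list[Seed]:
        groups: dict = {}
        for s in items:
            groups.setdefault(same_group(s), []).append(s)
        out = []
        for key in sorted(groups):
            run = sorted(groups[key], key=_seed_key)
            cur = run[0]
            for nxt in run[1:]:
                if close(cur, nxt):
                    cur = _fuse(cur, nxt)
                else:
                    out.append(cur)
                    cur = nxt
            out.append(cur)
        return out

    # gap-merging applies to single-model seeds; already-fused multi-model
    # seeds only merge further on overlap (keeps merging idempotent)
    pass1 = sweep(
        seeds,
        lambda s: (s.models, s.interval.seq_id, s.interval.strand),
        lambda a, b: (
            len(a.models) == 1
            and len(b.models) == 1
            and gap_distance(a.interval, b.interval) <= cfg.d_merge
        ) or overlap_len(a.interval, b.interval) >= 1,
    )
    # cross-model merge on overlap; sweeping sorted-by-start runs is
    # transitive because union intervals only grow rightwards
    pass2 = sweep(
        pass1,
        lambda s: (s.interval.seq_id, s.interval.strand),
        lambda a, b: overlap_len(a.interval, b.interval) >= 1,
    )
    pass2.sort(key=_seed_key)
    return pass2


def _window(seed: Seed, flank: int, seq_len: int) -> tuple[int, int]:
    return max(0, seed.interval.start - flank), min(seq_len, seed.interval.end + flank)


def _contains_seed(span: GenomicInterval, seed: Seed) -> bool:
    return (
        span.seq_id == seed.interval.seq_id
        and span.start <= seed.interval.start
        and span.end >= seed.interval.end
    )


def extend_seed(
    seed: Seed,
    contig: SeqRecord,
    ref_db: ReferenceDB,
    cfg: PipelineConfig = PipelineConfig(),
) -> ExtendedHit:
    """Match a seed (with flanks) against the reference database and adjust
    its boundaries to the best database hit that contains the whole seed.

    A qualifying full-IS (DNA) alignment wins over a transposase (ORF)
    alignment; with neither, the hit stays at catalytic-domain level with
    the seed's own interval. SeqID percentages are computed at both levels
    from the best qualifying alignment of each, normalised by the database
    item's full length.
    """
    L = len(contig.seq)
    best_orf: AlignmentHit | None = None
    if ref_db.orf_records:
        ws, we = _window(seed, cfg.context_orf, L)
        for hit in translated_search(contig.seq[ws:we], ws, contig.id, ref_db.orf_records):
            if _contains_seed(hit.query_span, seed):
                if best_orf is None or hit_order_key(hit) < hit_order_key(best_orf):
                    best_orf = hit
    best_dna: AlignmentHit | None = None
    if ref_db.is_records:
        ws, we = _window(seed, cfg.context_dna, L)
        window = contig.seq[ws:we]
        for rec in ref_db.is_records:
            hit = local_align_dna(window, rec.seq, rec.id, ws, contig.id)
            if hit is not None and _contains_seed(hit.query_span, seed):
                if best_dna is None or hit_order_key(hit) < hit_order_key(best_dna):
                    best_dna = hit
    seqid_dna = (
        100.0 * best_dna.identities / ref_db.is_len[best_dna.db_id] if best_dna else 0.0
    )
    orf_len = {r.id: len(r.seq) for r in ref_db.orf_records}
    seqid_orf = 100.0 * best_orf.identities / orf_len[best_orf.db_id] if best_orf else 0.0
    strand = seed.interval.strand
    if best_dna is not None:
        iv = replace(best_dna.query_span, strand=strand)
        return ExtendedHit(seed, iv, "dna", best_dna.db_id,
                           best_orf.db_id if best_orf else None,
                           min(seqid_dna, 100.0), min(seqid_orf, 100.0))
    if best_orf is not None:
        iv = replace(best_orf.query_span, strand=strand)
        return ExtendedHit(seed, iv, "orf", None, best_orf.db_id,
                           0.0, min(seqid_orf, 100.0))
    return ExtendedHit(seed, seed.interval, "domain")


def _hit_rank(h: ExtendedHit):
    return (-h.bit_score, -(len(h.interval)), h.interval.seq_id,
            h.interval.start, h.interval.end, h.models)


def filter_hits(
    hits: list[ExtendedHit],
    models: list[ProfileHMM],
    cfg: PipelineConfig = PipelineConfig(),
) -> list[ExtendedHit]:
    """Noise-cutoff, minimum-length and duplicate filtering.

    A hit is dropped when the seed's best bit score is below the noise
    cutoff of the model that produced it, or when its interval is shorter
    than ``cfg.L_min_nt``. Among hits overlapping by at least
    ``dup_overlap_frac`` of the shorter interval, the best one (higher
    score, then longer, then leftmost) survives. The result is independent
    of input order.
    """
    nc = {m.name: (m.noise_cutoff or 0.0) for m in models}
    survivors = []
    for h in hits:
        if h.seed.bit_score < nc.get(h.seed.best_model, 0.0):
            continue
        if len(h.interval) < cfg.L_min_nt:
            continue
        survivors.append(h)
    survivors.sort(key=_hit_rank)
    kept: list[ExtendedHit] = []
    for h in survivors:
        dup = False
        for k in kept:
            ov = overlap_len(h.interval, k.interval)
            shorter = min(len(h.interval), len(k.interval))
            if ov >= cfg.dup_overlap_frac * shorter:
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: (h.interval.seq_id, h.interval.start, h.interval.end))
    return kept


def run_pipeline(
    genome,
    models,
    ref_db: ReferenceDB,
    features=None,
    singles=(),
    cfg: PipelineConfig = PipelineConfig(),
    outdir=None,
):
    """Full search: seed, merge, extend, filter, classify, optionally write.

    Parameters may be paths (FASTA genome, HMM file) or already-loaded
    objects. Returns the classified hits; when ``outdir`` is given, also
    writes ``hits.csv``, ``hits.gff3`` and ``summary.txt`` there.
    """
    from . import classify as _classify
    from .phmm import read_hmm
    from .seqio import read_fasta, read_genbank_features, write_csv, write_gff3, write_summary

    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        genome = read_fasta(genome, "nt")
    if isinstance(models, (str, bytes)) or hasattr(models, "__fspath__"):
        models = read_hmm(models)
    if isinstance(features, (str, bytes)) or hasattr(features, "__fspath__"):
        features = read_genbank_features(features)

    log.info("seeding: %d contigs, %d profiles", len(genome), len(models) + len(singles))
    seeds = seed_scan(genome, models, singles, cfg)
    log.info("seeding found %d raw seeds", len(seeds))
    seeds = merge_seeds(seeds, cfg)
    log.info("merged to %d seeds", len(seeds))
    # seeds already below their model's noise cutoff are dropped by
    # filter_hits whatever extension finds, so skip their extension
    nc = {m.name: (m.noise_cutoff or 0.0) for m in list(models) + list(singles)}
    seeds = [s for s in seeds if s.bit_score >= nc.get(s.best_model, 0.0)]
    log.info("%d seeds at or above the noise cutoff", len(seeds))
    contigs = {rec.id: rec for rec in genome}
    extended = [extend_seed(s, contigs[s.interval.seq_id], ref_db, cfg) for s in seeds]
    hits = filter_hits(extended, list(models) + list(singles), cfg)
    log.info("%d hits after filtering", len(hits))
    classified = _classify.classify_hits(hits, features, cfg)
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_csv(classified, os.path.join(outdir, "hits.csv"))
        write_gff3(classified, os.path.join(outdir, "hits.gff3"))
        write_summary(
            classified,
            {rec.id: len(rec.seq) for rec in genome},
            os.path.join(outdir, "summary.txt"),
        )
    return classified
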