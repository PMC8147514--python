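"""Synthetic fixtures: catalytic-domain families, reference databases,
genomes with planted IS elements, decoy proteomes and toy GenBank
annotations.

The generator emulates the structure the detector targets — an IS element
is a transposase ORF whose protein carries a conserved catalytic domain,
wrapped in terminal inverted repeats and flanked on insertion by a direct
repeat (target-site duplication) — over uniform-random background
composition. Every artefact is deterministic given ``FixtureSpec.rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomicInterval, reverse_complement
from .phmm import AMINO, ProfileHMM, build_from_msa
from .seqio import AnnotationFeature, SeqRecord

__all__ = [
    "FixtureSpec",
    "Family",
    "PlantedTruth",
    "make_family",
    "make_families",
    "plant_genome",
    "make_decoys",
    "build_reference_db",
    "build_models",
    "write_fixtures",
]

_NT = np.array(list("ACGT"))
_AA = np.array(list(AMINO))

# codon choices per amino acid, translation table 11
_CODONS: dict[str, list[str]] = {}
from Bio.Data import CodonTable as _CT

for _codon, _aa in _CT.unambiguous_dna_by_id[11].forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic benchmark.

    Defaults: 3 catalytic-domain families of 12 members each (the model
    builder's minimum is 10), 100-aa domains diverged by i.i.d.
    substitution at rate 0.15, a 200 kb uniform background genome with 6
    planted IS copies, 20 bp terminal inverted repeats, 8 bp target-site
    duplications, and a 60-protein decoy proteome for noise-cutoff
    calibration.
    """

    rng_seed: int = 0
    n_families: int = 3
    seqs_per_family: int = 12
    domain_len_aa: int = 100
    within_family_sub_rate: float = 0.15
    genome_len: int = 200_000
    n_planted: int = 6
    ir_len: int = 20
    dr_len: int = 8
    decoy_count: int = 300
    decoy_len_aa: int = 300
    tpase_nterm_aa: int = 60
    tpase_cterm_aa: int = 40

    def __post_init__(self) -> None:
        if self.seqs_per_family < 1:
            raise ValueError("seqs_per_family must be positive")


@dataclass(frozen=True)
class Family:
    """One synthetic catalytic-domain family with its reference entries."""

    name: str
    msa: tuple[str, ...]
    consensus: str
    tpase_aa: str
    is_nt: str
    is_id: str
    orf_id: str


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth: where the elements were planted."""

    elements: tuple  # of (GenomicInterval, family_name, element_nt)

    def __len__(self) -> int:
        return len(self.elements)


def _rand_seq(rng, letters, length) -> str:
    return "".join(rng.choice(letters, size=length))


def _mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _back_translate(rng, aa: str) -> str:
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in aa)


def make_family(spec: FixtureSpec, family_idx: int) -> Family:
    """Sample one family: a consensus domain, ``seqs_per_family`` members
    diverged at ``within_family_sub_rate``, a transposase protein carrying
    the domain, and a full IS element with terminal inverted repeats."""
    rng = np.random.default_rng([spec.rng_seed, 1, family_idx])
    name = f"fam{family_idx}"
    consensus = _rand_seq(rng, _AA, spec.domain_len_aa)
    msa = tuple(
        _mutate(rng, consensus, spec.within_family_sub_rate)
        for _ in range(spec.seqs_per_family)
    )
    domain_variant = _mutate(rng, consensus, spec.within_family_sub_rate)
    tpase_aa = (
        "M"
        + _rand_seq(rng, _AA, spec.tpase_nterm_aa - 1)
        + domain_variant
        + _rand_seq(rng, _AA, spec.tpase_cterm_aa)
    )
    ir = _rand_seq(rng, _NT, spec.ir_len)
    spacer5 = _rand_seq(rng, _NT, 30)
    spacer3 = _rand_seq(rng, _NT, 20)
    orf = _back_translate(rng, tpase_aa) + "TAA"
    is_nt = ir + spacer5 + orf + spacer3 + reverse_complement(ir)
    return Family(
        name=name,
        msa=msa,
        consensus=consensus,
        tpase_aa=tpase_aa,
        is_nt=is_nt,
        is_id=f"IS_{name}",
        orf_id=f"tp_{name}",
    )


def make_families(spec: FixtureSpec) -> list[Family]:
    return [make_family(spec, i) for i in range(spec.n_families)]


def build_models(
    families: list[Family], min_train: int = 10
) -> list[ProfileHMM]:
    """Profile HMMs built from each family's alignment."""
    return [build_from_msa(list(f.msa), f.name, min_train=min_train) for f in families]


def build_reference_db(families: list[Family]):
    """Reference database records mirroring a curated IS collection: full
    elements (nt) and transposase ORFs (aa), headers linked by tokens."""
    from .pipeline import ReferenceDB

    is_records = [
        SeqRecord(f"{f.is_id}|family={f.name}", f.is_nt, "nt") for f in families
    ]
    orf_records = [
        SeqRecord(f"{f.orf_id}|is_id={f.is_id}|family={f.name}", f.tpase_aa, "aa")
        for f in families
    ]
    return ReferenceDB(is_records, orf_records)


def plant_genome(
    spec: FixtureSpec, families: list[Family], seq_id: str = "contig1"
):
    """A uniform-random background genome with ``n_planted`` IS copies.

    Families are planted round-robin, on random strands, each copy flanked
    by a ``dr_len`` target-site duplication. Returns (genome record,
    PlantedTruth, features) where features is a GenBank-style annotation
    containing a transposase CDS per planted element plus distractor CDSs
    (hypothetical proteins, a housekeeping gene, and an integrase record
    overlapping one planted copy).
    """
    rng = np.random.default_rng([spec.rng_seed, 2])
    if spec.n_planted == 0:
        seq = _rand_seq(rng, _NT, spec.genome_len)
        return SeqRecord(seq_id, seq, "nt"), PlantedTruth(()), {seq_id: []}
    max_elem = max(len(f.is_nt) for f in families)
    margin = max_elem + 2 * spec.dr_len + 200
    if spec.genome_len < spec.n_planted * margin:
        raise ValueError("genome too short to plant the requested copies")
    # insertion points in background coordinates, separated by >= margin
    for _attempt in range(100):
        points = np.sort(rng.integers(200, spec.genome_len - 200, spec.n_planted))
        if all(points[i + 1] - points[i] >= margin for i in range(len(points) - 1)):
            break
    else:
        raise RuntimeError("could not place planted elements without overlap")
    points = [int(p) for p in points]
    background = _rand_seq(rng, _NT, spec.genome_len)
    pieces = []
    truth = []
    features: list[AnnotationFeature] = []
    cursor = 0
    out_len = 0
    for i, p in enumerate(points):
        fam = families[i % len(families)]
        strand = "+" if rng.random() < 0.5 else "-"
        elem = fam.is_nt if strand == "+" else reverse_complement(fam.is_nt)
        dr = _rand_seq(rng, _NT, spec.dr_len)
        pieces.append(background[cursor:p])
        out_len += p - cursor
        pieces.append(dr)
        out_len += spec.dr_len
        start = out_len
        pieces.append(elem)
        out_len += len(elem)
        truth.append((GenomicInterval(seq_id, start, out_len, strand), fam.name, elem))
        features.append(
            AnnotationFeature(
                "CDS",
                GenomicInterval(seq_id, start, out_len, strand),
                {"product": [f"{fam.name} family transposase"]},
            )
        )
        pieces.append(dr)
        out_len += spec.dr_len
        cursor = p
    pieces.append(background[cursor:])
    out_len += spec.genome_len - cursor
    genome = "".join(pieces)
    assert len(genome) == out_len

    # distractor annotation in element-free background
    def free_spot(width: int) -> GenomicInterval:
        for _ in range(200):
            s = int(rng.integers(0, out_len - width))
            iv = GenomicInterval(seq_id, s, s + width, "+")
            if all(
                not (iv.start < t[0].end + spec.dr_len and t[0].start - spec.dr_len < iv.end)
                for t in truth
            ):
                return iv
        raise RuntimeError("no free spot for a distractor feature")

    for _ in range(3):
        features.append(
            AnnotationFeature("CDS", free_spot(600), {"product": ["hypothetical protein"]})
        )
    features.append(
        AnnotationFeature("CDS", free_spot(2400), {"product": ["DNA gyrase subunit A"]})
    )
    # a misannotated transposase: an integrase record over one planted copy
    first = truth[0][0]
    features.append(
        AnnotationFeature(
            "CDS",
            GenomicInterval(seq_id, first.start, first.end, first.strand),
            {"product": ["integrase"]},
        )
    )
    # a pseudo/incomplete fragment record (ignored by classification)
    features.append(
        AnnotationFeature(
            "CDS",
            free_spot(300),
            {"product": ["IS family transposase"], "pseudo": [""], "note": ["incomplete"]},
            pseudo_incomplete=True,
        )
    )
    features.sort(key=lambda f: f.interval.start)
    return SeqRecord(seq_id, genome, "nt"), PlantedTruth(tuple(truth)), {seq_id: features}


def make_decoys(spec: FixtureSpec, families: list[Family] | None = None) -> list[SeqRecord]:
    """Random background proteins for noise-cutoff calibration; none
    contains any family's consensus domain as a substring."""
    rng = np.random.default_rng([spec.rng_seed, 3])
    consensi = [f.consensus for f in families] if families else []
    out = []
    i = 0
    while len(out) < spec.decoy_count:
        seq = "M" + _rand_seq(rng, _AA, spec.decoy_len_aa - 1)
        i += 1
        if any(c in seq for c in consensi):
            continue
        out.append(SeqRecord(f"decoy{len(out)}", seq, "aa"))
    return out


def _genbank_record(genome: SeqRecord, features: list[AnnotationFeature]):
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord as BioRecord

    rec = BioRecord(Seq(genome.seq), id=genome.id, name=genome.id[:16],
                    description="synthetic fixture")
    rec.annotations["molecule_type"] = "DNA"
    for f in features:
        qualifiers = dict(f.qualifiers)
        loc = SimpleLocation(
            int(f.interval.start), int(f.interval.end),
            1 if f.interval.strand == "+" else -1,
        )
        rec.features.append(SeqFeature(loc, type=f.ftype, qualifiers=qualifiers))
    return rec


def write_fixtures(spec: FixtureSpec, outdir) -> dict:
    """Emit a complete fixture set under ``outdir``: genome FASTA, GenBank
    annotation, profile file, reference databases, decoys and truth CSV.
    Returns the paths."""
    import os

    from Bio import SeqIO as BioSeqIO

    from .phmm import write_hmm

    from .phmm import calibrate_evalue, calibrate_noise_cutoff

    os.makedirs(outdir, exist_ok=True)
    families = make_families(spec)
    genome, truth, features = plant_genome(spec, families)
    decoys = make_decoys(spec, families)
    models = build_models(families)
    # fixture profiles ship fully calibrated, as curated libraries would
    for i, m in enumerate(models):
        calibrate_evalue(m, 200, 200, rng_seed=spec.rng_seed * 1000 + i)
        calibrate_noise_cutoff(m, decoys)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "genbank": os.path.join(outdir, "genome.gbk"),
        "models": os.path.join(outdir, "families.hmm"),
        "db_is": os.path.join(outdir, "is_db.fasta"),
        "db_orf": os.path.join(outdir, "tpase_db.fasta"),
        "decoys": os.path.join(outdir, "decoys.fasta"),
        "truth": os.path.join(outdir, "truth.csv"),
    }
    with open(paths["genome"], "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.seq), 80):
            fh.write(genome.seq[i : i + 80] + "\n")
    BioSeqIO.write(_genbank_record(genome, features[genome.id]), paths["genbank"], "genbank")
    write_hmm(models, paths["models"])
    ref = build_reference_db(families)
    for key, records in (("db_is", ref.is_records), ("db_orf", ref.orf_records)):
        with open(paths[key], "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.seq}\n")
    with open(paths["decoys"], "w") as fh:
        for r in decoys:
            fh.write(f">{r.id}\n{r.seq}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("seq_id,start,end,strand,full_length,family\n")
        for iv, fam, _seq in truth.elements:
            fh.write(f"{iv.seq_id},{iv.start},{iv.end},{iv.strand},1,{fam}\n")
    return paths
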