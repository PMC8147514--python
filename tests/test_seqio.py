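"""Format IO: FASTA, GenBank features, GFF3 round-trip, CSV, summary."""

import textwrap

import pytest

from isdetect.classify import ClassifiedHit
from isdetect.genome import GenomicInterval
from isdetect.pipeline import ExtendedHit, Seed
from isdetect.seqio import (
    SeqRecord,
    read_fasta,
    read_genbank_features,
    read_gff3,
    write_csv,
    write_gff3,
    write_summary,
)


def make_hit(start, end, strand="+", score=20.0, level="domain", seq_id="c1",
             seqid_dna=0.0, seqid_orf=0.0, gb="NA", models=("fam0",),
             best_is=None, best_orf=None):
    seed = Seed(GenomicInterval(seq_id, start, end, strand), tuple(models), score, 1e-5, models[0])
    hit = ExtendedHit(seed, seed.interval, level, best_is, best_orf, seqid_dna, seqid_orf)
    return ClassifiedHit(hit, "improbable", "improbable", gb)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGT\n")
        recs = read_fasta(p)
        assert len(recs) == 1 and recs[0].id == "s1" and len(recs[0]) == 4

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_wrapped_lines_and_order(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\nACGT\n>b\nGG\nGG\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].seq == "ACGTACGT" and recs[1].seq == "GGGG"

    def test_case_folded_and_u_to_t(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nacgu\n")
        assert read_fasta(p)[0].seq == "ACGT"

    def test_record_validation(self):
        with pytest.raises(ValueError):
            SeqRecord("", "ACGT", "nt")
        with pytest.raises(ValueError):
            SeqRecord("x", "AC!T", "nt")
        with pytest.raises(ValueError):
            SeqRecord("x", "MKLB", "aa")  # B not in the protein alphabet


GENBANK = textwrap.dedent("""\
    LOCUS       c1                        60 bp    DNA     linear   BCT 01-JAN-2020
    DEFINITION  test.
    ACCESSION   c1
    FEATURES             Location/Qualifiers
         source          1..60
                         /organism="synthetic"
         CDS             10..36
                         /product="transposase"
         CDS             complement(5..10)
                         /product="hypothetical protein"
         CDS             join(2..7,40..45)
                         /product="split gene"
         CDS             50..58
                         /product="IS fragment"
                         /pseudo
                         /note="incomplete transposase"
    ORIGIN
            1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
    //
    """)


class TestGenBank:
    @pytest.fixture()
    def feats(self, tmp_path):
        p = tmp_path / "a.gbk"
        p.write_text(GENBANK)
        return read_genbank_features(p)["c1"]

    def test_coordinate_conversion(self, feats):
        cds = [f for f in feats if f.qualifiers.get("product") == ["transposase"]][0]
        assert (cds.interval.start, cds.interval.end, cds.interval.strand) == (9, 36, "+")

    def test_complement_strand(self, feats):
        c = [f for f in feats if f.qualifiers.get("product") == ["hypothetical protein"]][0]
        assert (c.interval.start, c.interval.end, c.interval.strand) == (4, 10, "-")

    def test_join_locations_flattened(self, feats):
        spans = sorted(
            (f.interval.start, f.interval.end)
            for f in feats
            if f.qualifiers.get("product") == ["split gene"]
        )
        assert spans == [(1, 7), (39, 45)]

    def test_pseudo_incomplete_flag(self, feats):
        frag = [f for f in feats if "pseudo" in f.qualifiers][0]
        assert frag.pseudo_incomplete
        others = [f for f in feats if "pseudo" not in f.qualifiers]
        assert not any(f.pseudo_incomplete for f in others)


class TestGff3:
    def test_coordinate_convention_and_roundtrip(self, tmp_path):
        hits = [
            make_hit(0, 100, "+", 12.5),
            make_hit(200, 950, "-", 33.0, level="dna", seqid_dna=88.2,
                     best_is="IS_x", gb="IS-related"),
        ]
        p = tmp_path / "h.gff3"
        write_gff3(hits, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert lines[1].split("\t")[3:5] == ["1", "100"]
        parsed = read_gff3(p)
        for hit, (iv, score, attrs) in zip(hits, parsed):
            assert iv == hit.interval
            assert score == pytest.approx(hit.bit_score, abs=0.05)

    def test_empty_hits(self, tmp_path):
        p = tmp_path / "h.gff3"
        write_gff3([], p)
        assert p.read_text() == "##gff-version 3\n"

    def test_semicolon_percent_encoded(self, tmp_path):
        hits = [make_hit(0, 100, best_is="IS;odd", level="dna", seqid_dna=50.0)]
        p = tmp_path / "h.gff3"
        write_gff3(hits, p)
        body = p.read_text().splitlines()[1]
        assert "IS;odd" not in body and "IS%3Bodd" in body
        assert read_gff3(p)[0][2]["best_is"] == "IS;odd"


class TestCsvAndSummary:
    def test_csv_shape_and_na(self, tmp_path):
        p = tmp_path / "h.csv"
        write_csv([make_hit(0, 100)], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 2
        row = dict(zip(lines[0].split(","), lines[1].split(",")))
        assert row["genbank_class"] == "NA"
        assert row["seqid_dna"] == "0.00"  # 2-decimal formatting
        assert (row["start"], row["end"]) == ("1", "100")

    def test_summary_union_arithmetic(self, tmp_path):
        hits = [make_hit(0, 1000), make_hit(5000, 6000)]
        p = tmp_path / "s.txt"
        write_summary(hits, {"c1": 100_000}, p)
        text = p.read_text()
        assert "bp_covered\t2000" in text and "pct_of_input\t2.0" in text

    def test_summary_overlap_counted_once(self, tmp_path):
        hits = [make_hit(0, 1000), make_hit(500, 1500)]
        p = tmp_path / "s.txt"
        write_summary(hits, {"c1": 100_000}, p)
        assert "bp_covered\t1500" in p.read_text()

    def test_summary_zero_hits(self, tmp_path):
        p = tmp_path / "s.txt"
        write_summary([], {"c1": 1000}, p)
        text = p.read_text()
        assert "total_hits\t0" in text and "pct_of_input\t0.0" in text
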