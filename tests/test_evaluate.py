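"""Benchmark evaluation: reference matching, merged FPs, eIS/pNov/nIS,
and metric arithmetic."""

import itertools

import pytest

from isdetect.classify import ClassifiedHit
from isdetect.evaluate import (
    RefAnnotation,
    classify_mfp,
    compute_metrics,
    evaluate_hits,
    match_to_reference,
    merge_false_positives,
    similarity_histogram,
)
from isdetect.genome import GenomicInterval
from isdetect.pipeline import ExtendedHit, ReferenceDB, Seed
from isdetect.seqio import SeqRecord


def hit(start, end, strand="+", best_is=None, best_orf=None, seq="c1",
        seqid_dna=0.0, seqid_orf=0.0, gb="NA", score=20.0):
    s = Seed(GenomicInterval(seq, start, end, strand), ("fam0",), score, 1e-8, "fam0")
    level = "dna" if best_is else ("orf" if best_orf else "domain")
    e = ExtendedHit(s, s.interval, level, best_is, best_orf, seqid_dna, seqid_orf)
    sim_d = "intra" if seqid_dna > 70 else ("inter" if seqid_dna > 50 else "improbable")
    sim_o = "intra" if seqid_orf > 45 else ("inter" if seqid_orf > 25 else "improbable")
    return ClassifiedHit(e, sim_d, sim_o, gb)


def ref_of(*spans):
    return RefAnnotation.from_truth(
        (GenomicInterval("c1", s, e), True, "fam0") for s, e in spans
    )


class TestMatchToReference:
    def test_overlap_boundary_100(self):
        ref = ref_of((1000, 2000))
        tp, fn, fps, _ = match_to_reference([hit(1900, 2500)], ref)
        assert (tp, fn, len(fps)) == (1, 0, 0)
        tp, fn, fps, _ = match_to_reference([hit(1901, 2500)], ref)
        assert (tp, fn, len(fps)) == (0, 1, 1)

    def test_multiple_hits_collapse_to_one_tp(self):
        ref = ref_of((1000, 3000))
        hits = [hit(1000, 1500), hit(2000, 2600), hit(2800, 3200)]
        tp, fn, fps, support = match_to_reference(hits, ref)
        assert tp == 1 and fn == 0 and not fps
        assert len(support[0]) == 3

    def test_unmatched_reference_is_fn(self):
        ref = ref_of((1000, 2000), (8000, 9000))
        tp, fn, fps, _ = match_to_reference([hit(1000, 2000)], ref)
        assert (tp, fn) == (1, 1)

    def test_permutation_invariant(self):
        ref = ref_of((1000, 2000), (5000, 6000))
        hits = [hit(900, 1500), hit(5500, 6500), hit(10000, 10400)]
        base = match_to_reference(hits, ref)[:2]
        assert match_to_reference(hits[::-1], ref)[:2] == base


@pytest.fixture()
def ref_db():
    return ReferenceDB(
        [SeqRecord("IS_X|family=famX", "ACGT" * 300, "nt"),
         SeqRecord("IS_Y|family=famY", "ACGT" * 250, "nt")],
        [SeqRecord("tp_X|is_id=IS_X|family=famX", "MKLV" * 50, "aa")],
    )


class TestMergeFalsePositives:
    def test_adjacent_same_element_merge(self, ref_db):
        # IS_X has length 1200; gap 300 <= 1200
        fps = [hit(0, 500, best_is="IS_X|family=famX"),
               hit(800, 1300, best_is="IS_X|family=famX")]
        assert len(merge_false_positives(fps, ref_db)) == 1

    def test_gap_beyond_element_length_stays_split(self, ref_db):
        fps = [hit(0, 500, best_is="IS_X|family=famX"),
               hit(1800, 2300, best_is="IS_X|family=famX")]
        assert len(merge_false_positives(fps, ref_db)) == 2

    def test_different_elements_stay_split(self, ref_db):
        fps = [hit(0, 500, best_is="IS_X|family=famX"),
               hit(600, 1100, best_is="IS_Y|family=famY")]
        assert len(merge_false_positives(fps, ref_db)) == 2

    def test_orf_match_maps_to_parent_is(self, ref_db):
        fps = [hit(0, 500, best_is="IS_X|family=famX"),
               hit(800, 1300, best_orf="tp_X|is_id=IS_X|family=famX")]
        assert len(merge_false_positives(fps, ref_db)) == 1

    def test_no_db_match_stays_singleton(self, ref_db):
        fps = [hit(0, 500), hit(600, 1100)]
        assert len(merge_false_positives(fps, ref_db)) == 2

    def test_opposite_strands_stay_split(self, ref_db):
        fps = [hit(0, 500, best_is="IS_X|family=famX"),
               hit(800, 1300, strand="-", best_is="IS_X|family=famX")]
        assert len(merge_false_positives(fps, ref_db)) == 2


class TestClassifyMfp:
    @pytest.mark.parametrize(
        "gb,sim_dna,sim_orf,expected",
        [
            ("IS-related", "improbable", "improbable", "eIS"),
            ("IS-related", "intra", "intra", "eIS"),
            ("no-annotation", "intra", "improbable", "eIS"),
            ("no-annotation", "inter", "improbable", "pNov"),
            ("no-annotation", "improbable", "inter", "pNov"),
            ("no-annotation", "improbable", "improbable", "nIS"),
            ("other-annotation", "intra", "improbable", "nIS"),
        ],
    )
    def test_rules(self, gb, sim_dna, sim_orf, expected):
        assert classify_mfp(gb, sim_dna, sim_orf) == expected

    def test_full_truth_table(self):
        """Every combination of GenBank category and per-level similarity
        matches the hand-derived decision table."""
        sims = ("improbable", "inter", "intra")
        rank = {s: i for i, s in enumerate(sims)}
        checked = 0
        for gb, sd, so in itertools.product(
            ("IS-related", "no-annotation", "other-annotation"), sims, sims
        ):
            if gb == "IS-related":
                expected = "eIS"
            elif gb == "other-annotation":
                expected = "nIS"
            else:
                best = max(sd, so, key=rank.get)
                expected = {"intra": "eIS", "inter": "pNov", "improbable": "nIS"}[best]
            assert classify_mfp(gb, sd, so) == expected, (gb, sd, so)
            checked += 1
        assert checked == 27


class TestComputeMetrics:
    def test_rates_from_counts(self):
        r = compute_metrics(TP=43, FN=6, FP=11, eIS=6, pNov=0, nIS=5)
        assert round(r.Se, 2) == 0.88
        assert round(r.FDR, 2) == 20.37
        assert r.teIS == 49
        assert round(r.pNovDR, 2) == 0.0 and round(r.nISDR, 2) == 9.26

    def test_without_reference_denominator_is_mfp(self):
        r = compute_metrics(eIS=1051, pNov=50, nIS=56, N=1170, with_reference=False)
        assert r.mFP == 1157 and r.teIS == 1051
        assert round(r.pNovDR, 2) == 4.32 and round(r.nISDR, 2) == 4.84

    def test_all_zero(self):
        r = compute_metrics()
        assert (r.Se, r.FDR, r.pNovDR, r.nISDR, r.pnov_nis) == (0, 0, 0, 0, 0)

    def test_ratio_edge_cases(self):
        assert compute_metrics(eIS=1, pNov=0, nIS=5).pnov_nis == 0.0
        r = compute_metrics(eIS=1, pNov=3, nIS=0)
        assert not r.pnov_nis_defined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(TP=-1)


class TestHistogramAndEndToEnd:
    def test_histogram_binning_and_conservation(self, ref_db):
        fps = [
            hit(0, 500, best_is="IS_X|family=famX", seqid_dna=72.0, gb="IS-related"),
            hit(5000, 5500, best_is="IS_Y|family=famY", seqid_dna=33.0, gb="no-annotation"),
            hit(9000, 9500, gb="no-annotation"),
        ]
        mfps = merge_false_positives(fps, ref_db)
        df = similarity_histogram(mfps)
        dna = df[df.level == "dna"]
        row = dna[(dna.bin_lo == 70) & (dna.genbank_class == "IS-related")]
        assert row["count"].sum() == 1
        assert dna["count"].sum() == len(mfps)
        assert df[df.level == "orf"]["count"].sum() == len(mfps)

    def test_histogram_empty(self):
        assert similarity_histogram([]).empty

    def test_conservation_eis_pnov_nis(self, ref_db):
        ref = ref_of((100_000, 101_000))
        hits = [
            hit(100_000, 100_900),                      # TP
            hit(0, 500, best_is="IS_X|family=famX", seqid_dna=80.0, gb="IS-related"),
            hit(5000, 5600, seqid_orf=30.0, gb="no-annotation"),
            hit(9000, 9600, gb="other-annotation"),
        ]
        r = evaluate_hits(hits, ref, ref_db)
        assert r.TP == 1 and r.FN == 0 and r.FP == 3
        assert r.eIS + r.pNov + r.nIS == r.mFP == 3
        assert (r.eIS, r.pNov, r.nIS) == (1, 1, 1)
        assert r.teIS == r.TP + r.eIS
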