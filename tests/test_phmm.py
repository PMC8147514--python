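"""Profile-HMM model: builder rules, Viterbi search vs path enumeration,
Gumbel calibration, noise cutoff, HMMER3-dialect round-trip."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import gumbel_r

from isdetect.phmm import (
    AMINO,
    ProfileHMM,
    build_from_msa,
    best_score,
    calibrate_evalue,
    calibrate_noise_cutoff,
    read_hmm,
    score_to_evalue,
    viterbi_domain_search,
    write_hmm,
)
from isdetect.seqio import SeqRecord

from .oracles import brute_force_profile_best


class TestBuildFromMsa:
    def test_degenerate_msa_modal_residue_dominates(self):
        m = build_from_msa(["ACDE"] * 10, "fam")
        assert m.M == 4
        for j, res in enumerate("ACDE", start=1):
            assert m.match_p[j].argmax() == AMINO.index(res)

    def test_minimum_training_sequences_enforced(self):
        with pytest.raises(ValueError, match="at least 10"):
            build_from_msa(["ACDE"] * 9, "fam")
        # outlier singletons are admitted explicitly
        assert build_from_msa(["ACDE"], "outlier", min_train=1).M == 4

    def test_match_column_majority_rule(self):
        # column 2: 6/10 gaps -> not a match state; column 1 and 3 full
        rows = ["A-C"] * 6 + ["AGC"] * 4
        m = build_from_msa(rows, "fam")
        assert m.M == 2
        # exactly half residues (5/10) is not "> 50%" either
        rows = ["A-C"] * 5 + ["AGC"] * 5
        assert build_from_msa(rows, "fam").M == 2

    def test_transition_groups_normalised(self):
        m = build_from_msa(["AC-E", "A-DE", "ACDE"] * 4, "fam")
        for j in range(m.M + 1):
            for grp in ((0, 1, 2), (3, 4), (5, 6)):
                assert math.isclose(m.trans[j, list(grp)].sum(), 1.0, abs_tol=1e-9)

    def test_singleton_profile_prefers_consensus(self):
        m = build_from_msa(["ACDEFGHIKL"], "out", min_train=1)
        s_self = best_score(m, "ACDEFGHIKL")
        assert s_self > best_score(m, "LKIHGFEDCA")


class TestViterbiSearch:
    def test_dp_equals_path_enumeration(self):
        """DP score == exhaustive state-path maximum for all models with
        M <= 3 and targets up to length 4 over a reduced alphabet."""
        alph = "ABCD"
        rng = np.random.default_rng(11)
        models = []
        for M in (1, 2, 3):
            for _ in range(4):
                rows = [
                    "".join(rng.choice(list(alph + "--"), M + 1)) for _ in range(3)
                ]
                try:
                    models.append(build_from_msa(rows, f"m{M}", 1, alph))
                except ValueError:
                    continue
        assert len(models) >= 8
        targets = [
            "".join(t)
            for L in range(1, 5)
            for t in itertools.product(alph, repeat=L)
        ]
        # deterministic thinning keeps the check exhaustive in L<=2 and
        # broad above
        targets = targets[:20] + targets[20::7]
        checked = 0
        for model in models:
            for tgt in targets:
                dp = best_score(model, tgt)
                ref = brute_force_profile_best(model, tgt)
                assert dp == pytest.approx(ref, abs=1e-9), (model.name, tgt)
                checked += 1
        assert checked > 500

    def test_consensus_beats_all_single_substitutions(self):
        consensus = "ACDEF"
        m = build_from_msa([consensus] * 10, "fam")
        s0 = best_score(m, consensus)
        for pos in range(5):
            for res in AMINO:
                if res == consensus[pos]:
                    continue
                variant = consensus[:pos] + res + consensus[pos + 1 :]
                assert best_score(m, variant) <= s0

    def test_multi_domain_hits_never_overlap(self):
        m = build_from_msa(["ACDEFGHIKL"] * 10, "fam")
        target = "MM" + "ACDEFGHIKL" + "WW" + "ACDEFGHIKL" + "MM" + "ACDEFGHIKL"
        hits = viterbi_domain_search(m, target, 0.0)
        assert len(hits) == 3
        spans = sorted((h.aa_start, h.aa_end) for h in hits)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_stop_codon_blocks_domain(self):
        m = build_from_msa(["ACDEFGHIKL"] * 10, "fam")
        intact = viterbi_domain_search(m, "ACDEFGHIKL", 0.0)[0].bit_score
        split = viterbi_domain_search(m, "ACDEF*GHIKL", 0.0)
        assert all(h.bit_score < intact for h in split)

    def test_no_positive_scores_empty_result(self):
        m = build_from_msa(["AAAAAAAAAA"] * 10, "fam")
        assert viterbi_domain_search(m, "WWWWW", 0.0) == []


class TestEvalueCalibration:
    def test_known_gumbel_recovered_within_10pct(self):
        """ML fit on 1000 draws from Gumbel(lambda=0.7, tau=2.0)."""
        rng = np.random.default_rng(42)
        draws = gumbel_r.rvs(loc=2.0, scale=1 / 0.7, size=1000, random_state=rng)
        loc, scale = gumbel_r.fit(draws)
        assert 1 / scale == pytest.approx(0.7, rel=0.10)
        assert loc == pytest.approx(2.0, rel=0.10)

    def test_deterministic_given_seed(self):
        m = build_from_msa(["ACDEFGHIKL"] * 10, "fam")
        a = calibrate_evalue(m, 100, 60, rng_seed=5)
        b = calibrate_evalue(m, 100, 60, rng_seed=5)
        assert a == b

    def test_requires_minimum_sample(self):
        m = build_from_msa(["ACDEFGHIKL"] * 10, "fam")
        with pytest.raises(ValueError):
            calibrate_evalue(m, 50, 60, rng_seed=0)

    def test_score_to_evalue_closed_form(self):
        m = build_from_msa(["ACDEFGHIKL"] * 10, "fam")
        m.lambda_, m.tau = 0.7, 2.0
        assert score_to_evalue(m, 2.0, 1) == pytest.approx(1 - math.exp(-1), abs=1e-9)
        assert score_to_evalue(m, 1e6, 1) == pytest.approx(0.0, abs=1e-12)
        assert score_to_evalue(m, 5.0, 10) == pytest.approx(
            10 * score_to_evalue(m, 5.0, 1), rel=1e-12
        )
        # monotone decreasing in score; strictly so above tau (far below
        # tau the probability saturates at 1.0 in floating point)
        s = np.linspace(-5, 15, 30)
        e = [score_to_evalue(m, x) for x in s]
        assert all(a >= b for a, b in zip(e, e[1:]))
        e_hi = [score_to_evalue(m, x) for x in np.linspace(m.tau, m.tau + 10, 20)]
        assert all(a > b for a, b in zip(e_hi, e_hi[1:]))

    def test_uncalibrated_model_rejects_evalue(self):
        m = build_from_msa(["ACDEFGHIKL"] * 10, "fam")
        with pytest.raises(ValueError):
            score_to_evalue(m, 5.0)


class TestNoiseCutoff:
    def test_maximum_decoy_score(self, small_models):
        m = build_from_msa(["ACDEFGHIKLMNPQRSTVWY" * 3] * 10, "fam")
        hot = SeqRecord("d1", "ACDEFGHIKLMNPQRSTVWY" * 3, "aa")
        cool = SeqRecord("d2", "A" * 60, "aa")
        nc = calibrate_noise_cutoff(m, [hot, cool])
        assert nc == pytest.approx(best_score(m, hot.seq))

    def test_no_hits_defaults_to_zero(self):
        m = build_from_msa(["ACDEFGHIKL"] * 10, "fam")
        assert calibrate_noise_cutoff(m, [SeqRecord("d", "W" * 40, "aa")]) == 0.0

    def test_empty_decoy_set_rejected(self):
        m = build_from_msa(["ACDEFGHIKL"] * 10, "fam")
        with pytest.raises(ValueError):
            calibrate_noise_cutoff(m, [])

    def test_adding_decoys_never_decreases(self):
        rng = np.random.default_rng(3)
        m = build_from_msa(["ACDEFGHIKL"] * 10, "fam")
        decoys = [
            SeqRecord(f"d{i}", "".join(rng.choice(list(AMINO), 50)), "aa")
            for i in range(20)
        ]
        prev = 0.0
        for k in (5, 10, 20):
            nc = calibrate_noise_cutoff(m, decoys[:k])
            assert nc >= prev
            prev = nc


class TestHmmFileDialect:
    @pytest.fixture()
    def model(self):
        rows = ["ACDEFGHIKL", "ACDEFGHIKV", "ACDEWGHIKL"] * 4
        m = build_from_msa(rows, "famX")
        m.lambda_, m.tau = 0.693, 4.2
        m.noise_cutoff = 7.5
        return m

    def test_roundtrip(self, tmp_path, model):
        p = tmp_path / "m.hmm"
        write_hmm([model], p)
        (back,) = read_hmm(p)
        assert back.name == "famX" and back.M == model.M
        assert back.noise_cutoff == pytest.approx(7.5)
        assert back.lambda_ == pytest.approx(0.693, abs=1e-4)
        assert back.tau == pytest.approx(4.2, abs=1e-4)
        np.testing.assert_allclose(back.match_p[1:], model.match_p[1:], atol=1e-5)
        np.testing.assert_allclose(back.trans, model.trans, atol=1e-5)
        # scores agree on a probe sequence
        assert best_score(back, "ACDEFGHIKL") == pytest.approx(
            best_score(model, "ACDEFGHIKL"), abs=1e-3
        )

    def test_multi_model_file_order(self, tmp_path, model):
        m2 = build_from_msa(["WYWYW"] * 10, "famY")
        p = tmp_path / "mm.hmm"
        write_hmm([model, m2], p)
        names = [m.name for m in read_hmm(p)]
        assert names == ["famX", "famY"]

    def test_star_token_is_probability_zero(self, tmp_path, model):
        model.trans[3, 2] = 0.0  # forbid M3->D4
        model.trans[3, :3] /= model.trans[3, :3].sum()
        p = tmp_path / "m.hmm"
        write_hmm([model], p)
        assert "*" in p.read_text()
        (back,) = read_hmm(p)
        assert back.trans[3, 2] == 0.0

    def test_missing_mandatory_field_rejected(self, tmp_path):
        p = tmp_path / "bad.hmm"
        p.write_text("HMMER3/f\nNAME x\n")
        with pytest.raises(ValueError):
            read_hmm(p)

    def test_dialect_parses_with_pyhmmer(self, tmp_path, model):
        """The written amino-alphabet dialect is valid HMMER3 text as far
        as an independent parser is concerned."""
        pyhmmer = pytest.importorskip("pyhmmer")
        p = tmp_path / "m.hmm"
        write_hmm([model], p)
        with pyhmmer.plan7.HMMFile(str(p)) as fh:
            hmms = list(fh)
        assert len(hmms) == 1 and hmms[0].M == model.M
        np.testing.assert_allclose(
            np.asarray(hmms[0].match_emissions)[1:],
            model.match_p[1:],
            atol=1e-4,
        )
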