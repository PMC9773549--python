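"""Seed finding, extension, bit-score statistics, and oracle agreement."""

import math

import numpy as np
import pytest
from _oracle import has_exact_word, sw_score_both_strands

from probenet.aligner import (AlignmentParams, align_all, align_pair, bitscore,
                              extend_seed, find_seed_hits, hits_to_frame,
                              reverse_complement)
from probenet.simulate import random_sequence


def _mutate(seq: str, positions, table=str.maketrans("ACGT", "CGTA")) -> str:
    out = list(seq)
    for i in positions:
        out[i] = out[i].translate(table)
    return "".join(out)


class TestSeeds:
    def test_exact_28mer_yields_one_seed(self):
        rng = np.random.default_rng(1)
        word = random_sequence(rng, 28)
        subject = random_sequence(rng, 100) + word + random_sequence(rng, 100)
        seeds = find_seed_hits(word, subject)
        assert [(q, s) for q, s, strand in seeds if strand == "+"] == [(0, 100)]

    def test_word_below_size_gives_no_seed(self):
        rng = np.random.default_rng(2)
        word = random_sequence(rng, 27)
        subject = random_sequence(rng, 50) + word + random_sequence(rng, 50)
        assert find_seed_hits(word, subject) == []

    def test_64mer_with_4_spread_substitutions_retains_a_seed(self):
        # substitutions >=28 apart leave at least one exact 28-window
        rng = np.random.default_rng(3)
        subject = random_sequence(rng, 64)
        query = _mutate(subject, [3, 10, 17, 24])
        # independent check by window enumeration
        windows = [query[i:i + 28] == subject[i:i + 28] for i in range(64 - 27)]
        assert any(windows)
        assert len(find_seed_hits(query, subject)) >= 1

    def test_n_bases_never_match(self):
        rng = np.random.default_rng(4)
        seq = random_sequence(rng, 28)
        subject = seq[:10] + "N" + seq[11:]
        assert find_seed_hits(seq, subject) == []

    def test_order_is_by_subject_then_query_position(self):
        word = "ACGT" * 7
        subject = "TT" + word + "GG" + word
        seeds = find_seed_hits(word + "AA" + word, subject)
        spositions = [s for _, s, _ in seeds]
        assert spositions == sorted(spositions)


class TestExtension:
    def test_perfect_match_is_full_identity_and_coverage(self):
        rng = np.random.default_rng(5)
        q = random_sequence(rng, 64)
        hit = align_pair(q, q)
        assert hit.mismatches == 0
        assert hit.percent_identity == 100.0
        assert hit.query_coverage == 100.0
        assert hit.raw_score == 64

    def test_64mer_with_4_mismatches_is_detected(self):
        # the detection anchor: 64-mers at 94% identity are reported
        rng = np.random.default_rng(6)
        subject = random_sequence(rng, 300)
        probe = _mutate(subject[100:164], [3, 10, 17, 24])
        hit = align_pair(probe, subject)
        assert hit is not None
        assert hit.mismatches == 4
        assert round(hit.percent_identity) == 94

    def test_unrelated_pair_has_no_hit_and_oracle_agrees(self):
        rng = np.random.default_rng(7)
        q = random_sequence(rng, 40)
        s = random_sequence(rng, 10_000)
        params = AlignmentParams()
        assert align_pair(q, s, params) is None
        best = sw_score_both_strands(q, s)
        assert bitscore(best, params) < params.min_bitscore_report

    def test_extend_seed_from_perfect_seed(self):
        rng = np.random.default_rng(8)
        s = random_sequence(rng, 200)
        q = s[50:114]
        seeds = find_seed_hits(q, s)
        hit = extend_seed(q, s, seeds[0])
        assert hit.raw_score == 64
        assert hit.subject_interval == (50, 114)

    def test_gapped_alignment_scores_like_oracle(self):
        rng = np.random.default_rng(9)
        s = random_sequence(rng, 160)
        q = s[10:60] + s[62:120]  # 2-nt deletion inside a long identity
        hit = align_pair(q, s)
        assert hit is not None
        assert hit.raw_score == sw_score_both_strands(q, s)
        assert hit.gap_chars >= 2


class TestBitscore:
    def test_monotone_in_raw_score(self):
        p = AlignmentParams()
        scores = [bitscore(s, p) for s in range(0, 200, 7)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_zero_bits_at_lnk_over_lambda(self):
        p = AlignmentParams()
        assert bitscore(math.log(p.karlin_k) / p.karlin_lambda, p) == pytest.approx(0.0)

    def test_matches_blastn_reported_bitscore_for_perfect_match(self):
        # blastn prints 119 for a perfect 64-nt megablast alignment
        pytest.importorskip("Bio")
        from probenet.io import blastn_available, run_blastn
        if not blastn_available():
            pytest.skip("blastn not installed")
        rng = np.random.default_rng(10)
        seq = random_sequence(rng, 64)
        frame = run_blastn([("q", seq)], [("s", seq)])
        ours = bitscore(64, AlignmentParams())
        assert float(frame.bitscore.iloc[0]) == pytest.approx(ours, abs=0.5)


class TestAlignAll:
    def test_identical_pair_gives_one_full_identity_row(self):
        rng = np.random.default_rng(11)
        seq = random_sequence(rng, 80)
        frame = hits_to_frame(align_all([("q", seq)], [("s", seq)]))
        assert len(frame) == 1
        assert frame.pident.iloc[0] == 100.0
        assert (frame.qstart.iloc[0], frame.qend.iloc[0]) == (1, 80)

    def test_reverse_strand_reported_with_descending_subject_coords(self):
        rng = np.random.default_rng(12)
        s = random_sequence(rng, 300)
        q = reverse_complement(s[100:180])
        frame = hits_to_frame(align_all([("q", q)], [("s", s)]))
        assert len(frame) == 1
        row = frame.iloc[0]
        assert row.sstart > row.send
        assert (row.send, row.sstart) == (101, 180)

    def test_one_substitution_near_end_of_38mer_is_detected(self):
        # the longer exact run (>=32 nt) contains a 28-word
        rng = np.random.default_rng(13)
        s = random_sequence(rng, 400)
        q = _mutate(s[200:238], [4])
        assert len(q) == 38
        windows = [q[i:i + 28] == s[200 + i:228 + i] for i in range(38 - 27)]
        assert any(windows)
        hits = align_all([("q", q)], [("s", s)])
        assert len(hits) == 1

    def test_strand_symmetry_of_raw_scores(self):
        rng = np.random.default_rng(14)
        s = random_sequence(rng, 500)
        q = _mutate(s[100:200], [10, 50, 90])
        fwd = align_all([("q", q)], [("s", s)])
        rev = align_all([("q", reverse_complement(q))], [("s", s)])
        assert [h.raw_score for h in fwd] == [h.raw_score for h in rev]
        assert fwd[0].strand != rev[0].strand

    def test_empty_query_set_raises(self):
        with pytest.raises(ValueError):
            align_all([], [("s", "ACGT" * 20)])


class TestOracleEquivalence:
    """Windowed seeded extension equals full-matrix Smith-Waterman."""

    @pytest.mark.parametrize("case_seed", range(40))
    def test_seeded_pairs_score_optimally(self, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        slen = int(rng.integers(60, 200))
        s = random_sequence(rng, slen)
        qlen = int(rng.integers(40, min(slen, 150)))
        start = int(rng.integers(0, slen - qlen + 1))
        q = s[start:start + qlen]
        # scatter substitutions and possibly a small indel outside one window
        n_mut = int(rng.integers(0, 4))
        positions = sorted(rng.choice(qlen, size=n_mut, replace=False)) if n_mut else []
        q = _mutate(q, positions)
        if rng.random() < 0.3 and qlen > 60:
            cut = int(rng.integers(35, qlen - 20))
            q = q[:cut] + q[cut + 1:]
        hit = align_pair(q, s)
        if hit is None:
            # detection requires a shared exact word on some strand
            assert not has_exact_word(q, s)
        else:
            assert hit.raw_score == pytest.approx(sw_score_both_strands(q, s))

    def test_self_alignment_scores_sequence_length(self):
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            n = int(rng.integers(28, 200))
            seq = random_sequence(rng, n)
            hit = align_pair(seq, seq)
            assert hit.percent_identity == 100.0
            assert hit.raw_score == n
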