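"""Alignment engine: exact-DP oracle agreement, strand symmetry, summaries."""

import numpy as np
import pytest

from nrscout.align import (
    AlignParams,
    AlignmentBlock,
    KarlinParams,
    KmerIndex,
    align_pair_dp,
    evalue,
    identity_and_coverage,
    local_align,
    revcomp,
)
from nrscout.errors import AlignmentSizeError, InputError

from .oracles import brute_force_local_align
from .conftest import mutate, rand_seq


class TestAlignPairDP:
    def test_self_alignment_is_perfect(self):
        rng = np.random.default_rng(0)
        a = rand_seq(300, rng)
        blk = align_pair_dp(a, a)
        assert blk.identity == 100.0
        assert blk.aln_columns == len(a)
        assert blk.gap_opens == 0

    def test_known_mismatch_example_matches_brute_force(self):
        a, b = "ACGTACGT", "ACGAACGT"
        params = AlignParams(match=1, mismatch=-2, gap_open=-3, gap_extend=-3)
        blk = align_pair_dp(a, b, params)
        score, matches, columns, identity = brute_force_local_align(
            a, b, match=1, mismatch=-2, gap=-3
        )
        assert (blk.matches, blk.aln_columns) == (matches, columns) == (7, 8)
        assert blk.identity == pytest.approx(identity) == 87.5
        assert blk.score == score

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_random_short_pairs_match_brute_force_score(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rand_seq(12, rng), rand_seq(14, rng)
        params = AlignParams(match=1, mismatch=-2, gap_open=-3, gap_extend=-3)
        blk = align_pair_dp(a, b, params)
        score, *_ = brute_force_local_align(a, b, 1, -2, -3)
        assert (blk.score if blk else 0) == score

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(7)
        a = rand_seq(200, rng)
        fwd = align_pair_dp(a, a)
        rc = align_pair_dp(a, revcomp(revcomp(a)))
        assert rc.score == fwd.score

    def test_size_cap_raises(self):
        rng = np.random.default_rng(1)
        a = rand_seq(100, rng)
        with pytest.raises(AlignmentSizeError):
            align_pair_dp(a, a, AlignParams(dp_cap=100))

    def test_non_dna_rejected(self):
        with pytest.raises(InputError):
            align_pair_dp("ACGTRYK", "ACGT")


class TestLocalAlign:
    @pytest.fixture(scope="class")
    def target(self):
        rng = np.random.default_rng(11)
        seq = rand_seq(100_000, rng)
        return seq, KmerIndex({"chr1": seq})

    def test_exact_substring_full_identity_and_coverage(self, target):
        seq, idx = target
        q = seq[5000:6000]
        blocks = local_align(q, idx)
        ident, cov = identity_and_coverage(blocks, len(q))
        assert ident == 100.0
        assert cov == 100.0
        assert blocks[0].target_start == 5000
        assert blocks[0].gap_opens == 0

    def test_unrelated_query_has_no_credible_hit(self, target):
        # independent random sequence must not reach 80% identity / 50% cover
        _seq, idx = target
        rng = np.random.default_rng(7)
        q = rand_seq(1000, rng)
        blocks = local_align(q, idx)
        qualifying = [b for b in blocks if b.identity >= 80]
        ident, cov = (
            identity_and_coverage(qualifying, len(q)) if qualifying else (0.0, 0.0)
        )
        assert cov < 50.0
        # cross-check the strongest hit with the exact DP oracle on its window
        if blocks:
            b = blocks[0]
            win = _seq[max(0, b.target_start - 100) : b.target_end + 100]
            dp = align_pair_dp(q, win)
            assert dp is None or (dp.query_end - dp.query_start) < 0.5 * len(q)

    def test_divergent_copy_identity_close_to_dp(self, target):
        seq, idx = target
        rng = np.random.default_rng(1)
        q = mutate(seq[20000:21000], 0.05, rng)
        blocks = local_align(q, idx)
        dp = align_pair_dp(q, seq[20000:21000])
        assert abs(blocks[0].identity - dp.identity) <= 2.0

    def test_reverse_strand_reports_forward_coordinates(self, target):
        seq, idx = target
        q = seq[40000:40500]
        fwd = local_align(q, idx)[0]
        rev = local_align(revcomp(q), idx)[0]
        assert rev.strand == "-"
        assert (rev.target_start, rev.target_end) == (fwd.target_start, fwd.target_end)
        assert rev.score == fwd.score
        assert (rev.query_start, rev.query_end) == (
            len(q) - fwd.query_end,
            len(q) - fwd.query_start,
        )

    def test_empty_query_or_index(self):
        idx = KmerIndex({})
        assert local_align("ACGTACGTACGTACGTACGT", idx) == []
        rng = np.random.default_rng(2)
        idx2 = KmerIndex({"c": rand_seq(1000, rng)})
        assert local_align("ACGT", idx2) == []  # shorter than k

    def test_seed_extend_tracks_dp_on_random_divergent_pairs(self):
        # moderate-size version of the engine-vs-oracle sweep
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(120, 500))
            a = rand_seq(n, rng)
            d = rng.uniform(0, 0.20)
            b = mutate(a, d, rng)
            dp = align_pair_dp(b, a)
            if dp is None or dp.score < 40:
                continue
            blocks = local_align(b, KmerIndex({"t": a}))
            assert blocks, f"no block at divergence {d:.2f}"
            assert blocks[0].score >= 0.9 * dp.score
            assert abs(blocks[0].identity - dp.identity) <= 2.0

    def test_embedded_divergent_region_is_reported_separately(self):
        # a ~15%-divergent interior stretch between near-identical flanks
        # must surface as its own low-identity block, not be absorbed
        rng = np.random.default_rng(5)
        t = rand_seq(20_000, rng)
        region = t[4000:7000]
        asm = region[:1000] + mutate(region[1000:2000], 0.15, rng) + region[2000:]
        blocks = local_align(asm, KmerIndex({"chr": t}))
        low = [b for b in blocks if b.identity < 90 and b.aln_columns >= 300]
        assert low, "divergent interior region was not split out"
        b = low[0]
        assert abs(b.query_start - 1000) < 60 and abs(b.query_end - 2000) < 60


class TestIdentityAndCoverage:
    def _block(self, qs, qe, matches=None, cols=None, score=1.0, qid="q"):
        cols = cols if cols is not None else qe - qs
        matches = matches if matches is not None else cols
        return AlignmentBlock(qid, qs, qe, "t", 0, cols, "+", matches, cols, 0, score)

    def test_empty_blocks(self):
        assert identity_and_coverage([], 500) == (0.0, 0.0)

    def test_union_counts_overlap_once(self):
        blocks = [self._block(0, 300), self._block(200, 450)]
        _, cov = identity_and_coverage(blocks, 500)
        assert cov == pytest.approx(90.0)

    def test_best_identity_from_top_scoring_block(self):
        blocks = [self._block(0, 300, matches=297, cols=300, score=250.0)]
        ident, cov = identity_and_coverage(blocks, 500)
        assert ident == pytest.approx(99.0)
        assert cov == pytest.approx(60.0)

    def test_invariant_to_order_and_abutting_split(self):
        whole = [self._block(100, 400)]
        split = [self._block(250, 400, score=0.5), self._block(100, 250)]
        assert identity_and_coverage(whole, 500)[1] == identity_and_coverage(split, 500)[1]

    def test_mixed_queries_rejected(self):
        with pytest.raises(InputError):
            identity_and_coverage(
                [self._block(0, 10), self._block(0, 10, qid="other")], 100
            )


class TestEvalue:
    def test_linear_in_database_length(self):
        kp = KarlinParams()
        assert evalue(30, 500, 2_000_000, kp) == pytest.approx(
            2 * evalue(30, 500, 1_000_000, kp)
        )

    def test_zero_score_gives_kmn(self):
        kp = KarlinParams(lambda_=1.28, K=0.46)
        assert evalue(0, 100, 1000, kp) == pytest.approx(0.46 * 100 * 1000)

    def test_direct_formula_value(self):
        # independent arithmetic: 0.46 * 500 * 1e6 * exp(-1.28 * 30)
        expected = 0.46 * 500 * 1e6 * float(np.exp(-38.4))
        assert evalue(30, 500, 10**6, KarlinParams(1.28, 0.46)) == pytest.approx(expected)

    def test_monotone_decreasing_in_score(self):
        kp = KarlinParams()
        es = [evalue(s, 500, 10**6, kp) for s in (10, 20, 30)]
        assert es[0] > es[1] > es[2]
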