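"""Extraction cascade: harvest, subtract, mask, merge, end-to-end recovery."""

import numpy as np
import pytest

from nrscout.align import AlignParams, AlignmentBlock, KmerIndex, local_align
from nrscout.errors import ConfigError
from nrscout.extract import (
    RepeatTrack,
    Segment,
    extract_assembly_nrs,
    mask_repeat_classes,
    merge_and_filter,
    subtract_high_identity,
    uncovered_segments,
)

from .conftest import rand_seq
from .oracles import merge_intervals_fixpoint


def _block(qid, qs, qe, identity):
    cols = qe - qs
    return AlignmentBlock(
        qid, qs, qe, "chr1", 0, cols, "+",
        matches=int(round(cols * identity / 100)), aln_columns=cols,
        gap_opens=0, score=float(cols),
    )


class TestUncoveredSegments:
    def test_fully_covered_contig_yields_nothing(self):
        asm = {"c": "A" * 5000}
        assert uncovered_segments(asm, [_block("c", 0, 5000, 100.0)]) == []

    def test_low_identity_coverage_counts_as_uncovered(self):
        # identity-85 coverage of [4000,7000) does not protect those bases
        asm = {"c": "A" * 10_000}
        blocks = [_block("c", 0, 4000, 95.0), _block("c", 4000, 7000, 85.0)]
        segs = uncovered_segments(asm, blocks)
        assert [(s.start, s.end) for s in segs] == [(4000, 10_000)]

    def test_minimum_length_rule(self):
        # whole contigs with no alignment: 120 bp kept, 90 bp discarded
        asm = {"long": "A" * 120, "short": "A" * 90}
        segs = uncovered_segments(asm, [])
        assert [(s.contig_id, s.start, s.end) for s in segs] == [("long", 0, 120)]


class TestSubtractHighIdentity:
    def test_segment_without_reference_hits_unchanged(self):
        rng = np.random.default_rng(0)
        ref = {"chr1": rand_seq(20_000, rng)}
        asm = {"c": rand_seq(1000, rng)}
        idx = KmerIndex(ref)
        segs = [Segment("c", 0, 1000, "a")]
        out = subtract_high_identity(segs, asm, idx)
        assert [(s.start, s.end) for s in out] == [(0, 1000)]

    def test_high_identity_middle_is_cut_out(self):
        rng = np.random.default_rng(1)
        ref_seq = rand_seq(20_000, rng)
        ref = {"chr1": ref_seq}
        middle = ref_seq[5000:5400]  # exact 400 bp reference copy
        contig = rand_seq(300, rng) + middle + rand_seq(300, rng)
        asm = {"c": contig}
        out = subtract_high_identity([Segment("c", 0, 1000, "a")], asm, KmerIndex(ref))
        pieces = sorted((s.start, s.end) for s in out)
        assert len(pieces) == 2
        assert pieces[0][0] == 0 and pieces[1][1] == 1000
        assert abs(pieces[0][1] - 300) <= 15 and abs(pieces[1][0] - 700) <= 15


class TestMaskRepeatClasses:
    TRACK = RepeatTrack(
        [
            ("c", 400, 600, "simple_repeat"),
            ("c", 2000, 2300, "SINE/Alu"),
        ]
    )

    def test_simple_repeat_subtracted_te_kept(self):
        segs = [Segment("c", 0, 1000, "a"), Segment("c", 1900, 2400, "a")]
        out = mask_repeat_classes(segs, self.TRACK)
        assert [(s.start, s.end) for s in out] == [(0, 400), (600, 1000), (1900, 2400)]

    def test_segment_inside_simple_repeat_removed(self):
        out = mask_repeat_classes([Segment("c", 450, 550, "a")], self.TRACK)
        assert out == []

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigError):
            mask_repeat_classes([Segment("c", 0, 10, "a")], self.TRACK, {"bogus_class"})


class TestMergeAndFilter:
    def _segs(self, ivs):
        return [Segment("c", s, e, "a") for s, e in ivs]

    def test_gap_within_200_merges_and_len_400_kept(self):
        out = merge_and_filter(self._segs([(100, 300), (450, 600)]))
        assert [(s.start, s.end) for s in out] == [(100, 600)]

    def test_gap_201_does_not_merge_and_short_dropped(self):
        assert merge_and_filter(self._segs([(0, 150), (401, 550)]), 200, 400) == []
        # boundary: exactly 200 merges
        out = merge_and_filter(self._segs([(0, 150), (350, 550)]), 200, 400)
        assert [(s.start, s.end) for s in out] == [(0, 550)]

    def test_length_boundary_inclusive(self):
        assert [(s.start, s.end) for s in merge_and_filter(self._segs([(0, 400)]))] == [(0, 400)]
        assert merge_and_filter(self._segs([(0, 399)])) == []

    def test_order_independence(self):
        ivs = [(500, 700), (0, 300), (320, 460), (900, 1400)]
        a = merge_and_filter(self._segs(ivs))
        b = merge_and_filter(self._segs(ivs[::-1]))
        assert [(s.start, s.end) for s in a] == [(s.start, s.end) for s in b]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadratic_fixpoint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 25)
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, 5000))
            ivs.append((s, s + int(rng.integers(1, 800))))
        got = [(s.start, s.end) for s in merge_and_filter(self._segs(ivs), 200, 400)]
        assert sorted(got) == merge_intervals_fixpoint(ivs, 200, 400)


class TestExtractAssemblyNRS:
    def test_identical_assembly_yields_nothing(self):
        rng = np.random.default_rng(3)
        ref = {"chr1": rand_seq(50_000, rng)}
        asm = {"c1": ref["chr1"]}
        out = extract_assembly_nrs(asm, KmerIndex(ref), RepeatTrack([]), "a")
        assert out == []

    def test_planted_novel_sequence_recovered(self):
        rng = np.random.default_rng(4)
        ref_seq = rand_seq(60_000, rng)
        novel = rand_seq(1000, rng)
        asm = {"c1": ref_seq[:30_000] + novel + ref_seq[30_000:]}
        out = extract_assembly_nrs(asm, KmerIndex({"chr1": ref_seq}), RepeatTrack([]), "a")
        assert len(out) == 1
        rec = out[0]
        assert novel in rec.sequence or rec.sequence in novel
        assert abs(len(rec.sequence) - 1000) <= 30
        # provenance invariant
        assert asm[rec.source_contig][rec.source_start : rec.source_end] == rec.sequence

    def test_planted_simple_repeat_array_removed(self):
        rng = np.random.default_rng(5)
        ref_seq = rand_seq(60_000, rng)
        array = "AC" * 500
        asm = {"c1": ref_seq[:30_000] + array + ref_seq[30_000:]}
        track = RepeatTrack([("c1", 30_000, 31_000, "simple_repeat")])
        out = extract_assembly_nrs(asm, KmerIndex({"chr1": ref_seq}), track, "a")
        assert out == []

    def test_no_output_realigns_to_reference(self, small_cohort):
        # second-pass postcondition on a cohort assembly
        params = AlignParams()
        name = small_cohort.assembly_names[0]
        ref_idx = KmerIndex(small_cohort.reference.genome)
        out = extract_assembly_nrs(
            small_cohort.assemblies[name], ref_idx,
            small_cohort.assembly_tracks[name], name,
        )
        assert out
        for rec in out[:5]:
            blocks = local_align(rec.sequence, ref_idx, params, query_id=rec.nrs_id)
            high = [
                b for b in blocks
                if b.identity >= 90 and b.query_end - b.query_start >= 100
            ]
            assert not high, f"{rec.nrs_id} still aligns at >=90% identity"
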