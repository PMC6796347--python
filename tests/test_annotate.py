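"""Tandem detection, repeat profiles, TR association, transcription calls."""

import numpy as np
import pytest
from scipy import stats

from nrscout.align import KmerIndex, revcomp
from nrscout.annotate import (
    ReadMapParams,
    TandemParams,
    detect_tandem,
    quality_filter,
    repeat_profile,
    tandem_covered_mask,
    tandem_fraction,
    tr_association,
    transcription_support,
    RepeatProfile,
)
from nrscout.classify import NRSCall
from nrscout.errors import DegenerateInputError
from nrscout.extract import NRSRecord, RepeatTrack
from nrscout.place import Placement
from nrscout.simulate import simulate_reads

from .conftest import mutate, rand_seq
from .oracles import tandem_coverage_scan


class TestDetectTandem:
    def test_clean_trinucleotide_array(self):
        calls = detect_tandem("ACG" * 8)
        assert calls == [(0, 24, 3, pytest.approx(8.0))]

    def test_homopolymer_has_period_one(self):
        calls = detect_tandem("A" * 50)
        assert len(calls) == 1
        start, end, period, copies = calls[0]
        assert (start, end, period) == (0, 50, 1)
        assert copies == pytest.approx(50.0)

    def test_random_sequence_has_no_calls(self):
        rng = np.random.default_rng(11)
        assert detect_tandem(rand_seq(1000, rng)) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_coverage_identical_to_window_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = rand_seq(300, rng)
        # salt in a couple of arrays so coverage is non-trivial
        seq = seq[:100] + "TTAGGC" * 10 + seq[100:200] + "AT" * 20 + seq[200:]
        got = tandem_covered_mask(seq).tolist()
        want = tandem_coverage_scan(seq)
        assert got == want

    def test_reverse_complement_coverage_mirrors(self):
        rng = np.random.default_rng(3)
        seq = rand_seq(120, rng) + "CAGT" * 12 + rand_seq(120, rng)
        fwd = tandem_covered_mask(seq)
        rev = tandem_covered_mask(revcomp(seq))
        assert fwd.tolist() == rev[::-1].tolist()

    def test_noisy_array_within_mismatch_budget_detected(self):
        rng = np.random.default_rng(4)
        arr = mutate("ACGGATCAGGTTACGGATCAAGTC" * 20, 0.03, rng)
        frac = tandem_fraction(arr)
        assert frac > 0.9


class TestRepeatProfile:
    def _setup(self, rng):
        ref_seq = rand_seq(40_000, rng)
        placement = Placement("n", "precise", "chr1", 20_000, 21_000)
        call = NRSCall("n", "alternate", "chr1", 20_000, 21_000, 1000, 50.0, 1.0)
        return {"chr1": ref_seq}, placement, call

    def test_te_copy_has_full_internal_te_fraction(self):
        rng = np.random.default_rng(5)
        ref, placement, call = self._setup(rng)
        te = {"AluToy": rand_seq(300, rng)}
        nrs = mutate(te["AluToy"], 0.05, rng) * 2
        prof = repeat_profile(
            call, placement, nrs, ref, RepeatTrack([]), KmerIndex(te)
        )
        assert prof.te_fraction_internal > 0.9
        assert prof.tr_fraction_internal < 0.3

    def test_random_sequence_profiles_near_zero(self):
        rng = np.random.default_rng(6)
        ref, placement, call = self._setup(rng)
        prof = repeat_profile(
            call, placement, rand_seq(900, rng), ref, RepeatTrack([]), None
        )
        assert prof.te_fraction_internal == 0.0
        assert prof.tr_fraction_internal < 0.1
        assert prof.ref_tr_fraction < 0.1

    def test_tandem_alternate_and_reference_allele_both_tr_rich(self):
        rng = np.random.default_rng(7)
        ref_seq = rand_seq(40_000, rng)
        motif = rand_seq(20, rng)
        ref_allele = (motif * 60)[:1000]
        ref_seq = ref_seq[:20_000] + ref_allele + ref_seq[21_000:]
        alt_motif = mutate(motif, 0.3, rng)
        nrs = (alt_motif * 60)[:1200]
        placement = Placement("n", "precise", "chr1", 20_000, 21_000)
        call = NRSCall("n", "alternate", "chr1", 20_000, 21_000, 1000, 70.0, 1.2)
        prof = repeat_profile(call, placement, nrs, {"chr1": ref_seq}, RepeatTrack([]), None)
        assert prof.tr_fraction_internal > 0.5
        assert prof.ref_tr_fraction > 0.5

    def test_flank_te_fraction_from_reference_track(self):
        rng = np.random.default_rng(8)
        ref, placement, call = self._setup(rng)
        track = RepeatTrack([("chr1", 16_000, 18_500, "SINE/Alu")])
        prof = repeat_profile(call, placement, rand_seq(900, rng), ref, track, None)
        # 2500 bp of TE in 10 kb of flank windows
        assert prof.te_fraction_flank == pytest.approx(0.25)


class TestTrAssociation:
    def _profiles(self, x, y):
        return [
            RepeatProfile(f"p{i}", 0, xi, 0, 0, yi)
            for i, (xi, yi) in enumerate(zip(x, y))
        ]

    def test_perfect_line_gives_r2_one(self):
        x = [0.1, 0.3, 0.5, 0.8]
        slope, intercept, r2 = tr_association(self._profiles(x, x))
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_independent_noise_gives_r2_near_zero(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 400)
        y = rng.uniform(0, 1, 400)
        *_, r2 = tr_association(self._profiles(x, y))
        assert r2 < 0.05

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.2, 1.0, 100)
        y = 0.8 * x + rng.normal(0, 0.05, 100)
        slope, intercept, r2 = tr_association(self._profiles(x, y))
        res = stats.linregress(x, y)  # same draws, independent call path
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert slope == pytest.approx(sxy / sxx)
        assert r2 == pytest.approx(res.rvalue**2)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            tr_association(self._profiles([0.5, 0.5, 0.5], [0.1, 0.2, 0.3]))


class TestTranscriptionSupport:
    def test_no_evidence_sources_gives_all_untranscribed(self):
        rng = np.random.default_rng(10)
        recs = [NRSRecord("n1", rand_seq(800, rng), "a", "c", 0, 800)]
        out = transcription_support(recs, {}, {})
        assert out["n1"].transcribed is False

    def test_reads_from_selected_nrs_support_exactly_those(self):
        rng = np.random.default_rng(12)
        recs = [
            NRSRecord(f"n{i}", rand_seq(900, rng), "a", "c", 0, 900) for i in range(6)
        ]
        expressed = {r.nrs_id: r.sequence for r in recs[:2]}
        read_sets = {
            f"s{j}": simulate_reads(expressed, depth=20, seed=j, stream=7)
            for j in range(2)
        }
        out = transcription_support(recs, read_sets, {})
        assert {k for k, v in out.items() if v.rna_supported} == {"n0", "n1"}
        assert all(v.cpm["s0"] > 0 for k, v in out.items() if v.rna_supported)

    def test_single_sample_support_is_insufficient(self):
        rng = np.random.default_rng(13)
        recs = [NRSRecord("n0", rand_seq(900, rng), "a", "c", 0, 900)]
        reads = simulate_reads({"n0": recs[0].sequence}, depth=20, seed=1, stream=8)
        out = transcription_support(recs, {"only": reads}, {})
        assert out["n0"].supporting_samples == 1
        assert out["n0"].rna_supported is False

    def test_est_hit_ignores_query_coverage(self):
        rng = np.random.default_rng(14)
        seq = rand_seq(1200, rng)
        recs = [NRSRecord("n0", seq, "a", "c", 0, 1200)]
        est = {"est1": seq[500:620], "other": rand_seq(300, rng)}  # 10% coverage
        out = transcription_support(recs, {}, est)
        assert out["n0"].est_supported is True
        assert out["n0"].transcribed is True

    def test_quality_filter_drops_short_and_lowq(self):
        good = ("A" * 100, "I" * 100, "C" * 100, "I" * 100)
        short = ("A" * 50, "I" * 50, "C" * 100, "I" * 100)
        lowq = ("A" * 100, "#" * 100, "C" * 100, "I" * 100)
        kept = quality_filter([good, short, lowq])
        assert kept == [("A" * 100, "C" * 100)]
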