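"""Clustering, contamination screen, presence matrix, novelty, PCA."""

import numpy as np
import pandas as pd
import pytest

from nrscout.align import AlignParams, KmerIndex, align_pair_dp, revcomp
from nrscout.errors import DegenerateInputError, InputError
from nrscout.extract import NRSRecord
from nrscout.unify import (
    PresenceMatrix,
    build_presence_matrix,
    cluster_redundant,
    novelty_stratify,
    pca_occurrence,
    reciprocal_intersect,
    representatives,
    screen_contamination,
)

from .conftest import mutate, rand_seq


def _rec(nrs_id, seq, asm="a"):
    return NRSRecord(nrs_id, seq, asm, "c", 0, len(seq))


class TestClusterRedundant:
    def test_identical_sequences_merge_with_lexicographic_representative(self):
        rng = np.random.default_rng(0)
        s = rand_seq(1000, rng)
        clusters = cluster_redundant([_rec("b", s), _rec("a", s)])
        assert len(clusters) == 1
        assert clusters[0].representative == "a"
        assert sorted(clusters[0].members) == ["a", "b"]

    def test_partial_copy_clusters_by_coverage_of_shorter(self):
        # 500 bp sequence: 80% of it is a 96%-identity copy of the rep
        rng = np.random.default_rng(1)
        rep = rand_seq(2000, rng)
        short = mutate(rep[500:930], 0.03, rng) + rand_seq(70, rng)
        clusters = cluster_redundant([_rec("rep", rep), _rec("short", short)])
        assert len(clusters) == 1

    def test_independent_random_sequences_stay_apart(self):
        rng = np.random.default_rng(2)
        a, b = rand_seq(1000, rng), rand_seq(1000, rng)
        clusters = cluster_redundant([_rec("a", a), _rec("b", b)])
        assert len(clusters) == 2
        # oracle: no qualifying local alignment exists between the two
        blk = align_pair_dp(a, b)
        assert blk is None or (
            blk.identity < 95 or (blk.query_end - blk.query_start) < 0.8 * 1000
        )

    def test_reverse_complement_copies_cluster(self):
        rng = np.random.default_rng(3)
        s = rand_seq(800, rng)
        clusters = cluster_redundant([_rec("f", s), _rec("r", revcomp(s))])
        assert len(clusters) == 1

    def test_idempotent_on_representatives(self):
        rng = np.random.default_rng(4)
        recs = [_rec(f"s{i}", rand_seq(600, rng)) for i in range(4)]
        recs += [_rec("s0copy", recs[0].sequence)]
        clusters = cluster_redundant(recs)
        reps = representatives(clusters, recs)
        again = cluster_redundant(reps)
        assert all(len(c.members) == 1 for c in again)
        assert len(again) == len(clusters)

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        recs = [_rec(f"s{i}", rand_seq(500, rng)) for i in range(6)]
        clusters = cluster_redundant(recs)
        members = sorted(m for c in clusters for m in c.members)
        assert members == sorted(r.nrs_id for r in recs)
        assert all(c.representative in c.members for c in clusters)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            cluster_redundant([])


class TestScreenContamination:
    def test_empty_decoy_keeps_everything(self):
        rng = np.random.default_rng(6)
        recs = [_rec("a", rand_seq(500, rng))]
        kept, removed = screen_contamination(recs, {})
        assert [r.nrs_id for r in kept] == ["a"] and removed == []

    def test_exact_decoy_substring_removed_and_rescreen_stable(self):
        rng = np.random.default_rng(7)
        decoy = {"d": rand_seq(5000, rng)}
        contaminated = _rec("bad", decoy["d"][1000:1800])
        clean = _rec("good", rand_seq(800, rng))
        kept, removed = screen_contamination([contaminated, clean], decoy)
        assert [r.nrs_id for r in removed] == ["bad"]
        kept2, removed2 = screen_contamination(kept, decoy)
        assert removed2 == [] and len(kept2) == len(kept)

    def test_both_thresholds_required(self):
        # 95% identity over only 60% of the query -> kept
        rng = np.random.default_rng(8)
        decoy_core = rand_seq(600, rng)
        decoy = {"d": rand_seq(500, rng) + decoy_core + rand_seq(500, rng)}
        query = mutate(decoy_core, 0.03, rng) + rand_seq(400, rng)
        kept, removed = screen_contamination([_rec("q", query)], decoy)
        assert [r.nrs_id for r in kept] == ["q"]


class TestPresenceMatrix:
    @pytest.fixture(scope="class")
    def genomes(self):
        rng = np.random.default_rng(9)
        ref = rand_seq(30_000, rng)
        novel = rand_seq(900, rng)
        carrier = {"c": ref[:15_000] + novel + ref[15_000:]}
        non_carrier = {"c": ref}
        ape = {"c": mutate(ref[:15_000], 0.015, rng) + mutate(novel, 0.015, rng) + mutate(ref[15_000:], 0.015, rng)}
        return novel, {"h1": carrier, "h2": non_carrier, "ape": ape}

    def test_presence_and_pooled_non_private(self, genomes):
        novel, gset = genomes
        rec = NRSRecord("n1", novel, "h1", "c", 15_000, 15_900)
        pm = build_presence_matrix([rec], gset, human_names=["h1", "h2"])
        assert bool(pm.table.loc["n1", "h1"]) is True   # self-recovery
        assert bool(pm.table.loc["n1", "h2"]) is False
        assert bool(pm.table.loc["n1", "ape"]) is True  # 1.5% divergence ok
        # human + outgroup jointly counted: 2 occurrences -> non-private
        assert bool(pm.non_private.loc["n1"]) is True
        # 1 of 2 humans is not more than half of them
        assert bool(pm.major_allele.loc["n1"]) is False
        pm2 = PresenceMatrix(pm.table, ["h1"])
        assert bool(pm2.major_allele.loc["n1"]) is True

    def test_single_occurrence_is_private(self):
        table = pd.DataFrame({"g1": [True], "g2": [False], "g3": [False]}, index=["x"])
        pm = PresenceMatrix(table, ["g1", "g2", "g3"])
        assert bool(pm.non_private.loc["x"]) is False
        assert int(pm.occurrence_count.loc["x"]) == 1


class TestNoveltyStratify:
    def test_partition_by_joint_criteria(self):
        rng = np.random.default_rng(10)
        ref = rand_seq(40_000, rng)
        idx = KmerIndex({"chr1": ref})
        novel = _rec("novel", rand_seq(700, rng))
        # 85% identity over ~60% of the query -> residual
        residual = _rec("residual", mutate(ref[1000:1600], 0.12, rng) + rand_seq(400, rng))
        # 85% identity over only ~40% -> still "no alignment"
        low_cov = _rec("lowcov", mutate(ref[5000:5400], 0.12, rng) + rand_seq(600, rng))
        none_set, residual_set = novelty_stratify([novel, residual, low_cov], idx)
        assert sorted(r.nrs_id for r in none_set) == ["lowcov", "novel"]
        assert [r.nrs_id for r in residual_set] == ["residual"]


class TestReciprocalIntersect:
    def test_identical_sets_fully_shared(self):
        rng = np.random.default_rng(11)
        seqs = {f"s{i}": rand_seq(700, rng) for i in range(3)}
        assert reciprocal_intersect(seqs, dict(seqs)) == sorted(seqs)

    def test_disjoint_sets_share_nothing(self):
        rng = np.random.default_rng(12)
        a = {"a1": rand_seq(700, rng)}
        b = {"b1": rand_seq(700, rng)}
        assert reciprocal_intersect(a, b) == []

    def test_one_directional_hit_still_shared_by_union(self):
        # short A member covered well only in the B->A direction
        rng = np.random.default_rng(13)
        core = rand_seq(500, rng)
        a = {"a1": rand_seq(900, rng) + core}     # A->B: core is 36% of a1 -> no hit
        b = {"b1": core[:450]}                    # B->A: b1 covered 100% in a1
        assert reciprocal_intersect(a, b) == ["a1"]


class TestPCAOccurrence:
    def _two_groups(self):
        # 6 assemblies, two groups with disjoint private variant blocks
        data = {}
        for i in range(3):
            data[f"A{i}"] = [True] * 10 + [False] * 10
        for i in range(3):
            data[f"B{i}"] = [False] * 10 + [True] * 10
        return pd.DataFrame(data, index=[f"v{j}" for j in range(20)])

    def test_pc1_separates_groups_with_opposite_signs(self):
        coords, ev = pca_occurrence(self._two_groups())
        a = np.sign(coords.loc[["A0", "A1", "A2"], "PC1"].to_numpy())
        b = np.sign(coords.loc[["B0", "B1", "B2"], "PC1"].to_numpy())
        assert len(set(a)) == 1 and len(set(b)) == 1
        assert a[0] != b[0]
        assert ev[0] > 0.9

    def test_duplicated_column_gets_identical_coordinates(self):
        df = self._two_groups()
        df["A0dup"] = df["A0"]
        coords, _ = pca_occurrence(df)
        assert np.allclose(coords.loc["A0"], coords.loc["A0dup"])

    def test_explained_variance_fractions_valid(self):
        coords, ev = pca_occurrence(self._two_groups())
        assert ev.sum() <= 1.0 + 1e-9
        assert all(ev[i] >= ev[i + 1] for i in range(len(ev) - 1))

    def test_deterministic_sign_convention(self):
        c1, _ = pca_occurrence(self._two_groups())
        c2, _ = pca_occurrence(self._two_groups())
        assert np.allclose(c1.to_numpy(), c2.to_numpy())

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": [1, 1], "b": [1, 1], "c": [1, 1]}, dtype=float)
        with pytest.raises(DegenerateInputError):
            pca_occurrence(df)
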