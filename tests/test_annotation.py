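"""Exact/fuzzy/motif antigen matching, feature assignment, subsampled evenness."""

import numpy as np
import pytest

from tcrep.annotation import (
    ClusteredReference,
    assign_antigen_features,
    cluster_reference_db,
    match_exact,
    match_fuzzy,
    match_motif,
    subsampled_mean_evenness,
)
from tcrep.clustering import TCRCluster
from tcrep.core import Clonotype, DegenerateInputError, ReferenceDB

from conftest import make_repertoire


def clono(cdr3, v="TRBV19*01"):
    return Clonotype(cdr3_aa=cdr3, v_allele=v, j_allele="TRBJ2-7*01", count=1)


class TestMatchExact:
    db = ReferenceDB([("TRBV19", "CASSIRSSYEQYF", "NP177"),
                      ("TRBV9", "CASSIRSSYEQYF", "M158")])

    def test_identical_entry_matches(self):
        assert match_exact(clono("CASSIRSSYEQYF"), self.db) == ["NP177"]

    def test_same_cdr3_different_v_no_match(self):
        assert match_exact(clono("CASSIRSSYEQYF", v="TRBV28*01"), self.db) == []

    def test_one_substitution_no_match(self):
        assert match_exact(clono("CASSIRSTYEQYF"), self.db) == []


class TestMatchFuzzy:
    ref = ClusteredReference(
        global_entries=[("TRBV19", "CASSIRSSYEQYF", "NP177")], motifs={}
    )

    def test_one_substitution_matches(self):
        assert match_fuzzy(clono("CASSIRSTYEQYF"), self.ref) == ["NP177"]

    def test_two_substitutions_no_match(self):
        assert match_fuzzy(clono("CASSIRTTYEQYF"), self.ref) == []

    def test_length_mismatch_no_match(self):
        # deletion relative to the reference: substitution-only rule
        assert match_fuzzy(clono("CASSIRSYEQYF"), self.ref) == []

    def test_v_gene_must_agree(self):
        assert match_fuzzy(clono("CASSIRSTYEQYF", v="TRBV9*01"), self.ref) == []


class TestClusterReferenceDB:
    def test_hamming_neighbors_globally_clustered(self):
        db = ReferenceDB([
            ("TRBV19", "CASSIRSSYEQYF", "EpA"),
            ("TRBV19", "CASSIRSTYEQYF", "EpA"),
            ("TRBV19", "CASSIRSAYEQYF", "EpA"),
            ("TRBV9", "CASSWGWGWEQYF", "EpB"),  # singleton epitope group
        ])
        ref = cluster_reference_db(db)
        clustered = {cdr3 for _, cdr3, _ in ref.global_entries}
        assert clustered == {"CASSIRSSYEQYF", "CASSIRSTYEQYF", "CASSIRSAYEQYF"}

    def test_planted_motif_reaches_motif_set(self):
        rng = np.random.default_rng(12)
        letters = "ACDEFGHIKLMNPQRSTVY"
        bg_seqs = set()
        while len(bg_seqs) < 150:
            bg_seqs.add("CAS" + "".join(rng.choice(list(letters), 8)) + "YF")
        background = make_repertoire([1] * 150, cdr3s=sorted(bg_seqs))
        db = ReferenceDB([
            ("TRBV19", "CASWWWWAAAEQYF", "EpA"),
            ("TRBV19", "CASWWWWCCCEQYF", "EpA"),
            ("TRBV19", "CASWWWWDDDEQYF", "EpA"),
        ])
        ref = cluster_reference_db(db, background)
        assert any("WWWW" in m for m in ref.motifs)
        assert all(ref.motifs[m] == ("EpA",) for m in ref.motifs)


class TestMatchMotif:
    def test_equal_motif_annotates_cluster(self):
        clusters = [TCRCluster("C0", frozenset({"A" * 9, "B" * 9}), "motif", ("SIRS",))]
        ref = ClusteredReference(global_entries=[], motifs={"SIRS": ("EpA",)})
        assert match_motif(clusters, ref) == {"C0": ("EpA",)}

    def test_global_clusters_not_considered(self):
        clusters = [TCRCluster("C0", frozenset({"A" * 9, "B" * 9}), "global", ("SIRS",))]
        ref = ClusteredReference(global_entries=[], motifs={"SIRS": ("EpA",)})
        assert match_motif(clusters, ref) == {}

    def test_shared_motif_collects_both_epitopes(self):
        clusters = [TCRCluster("C0", frozenset({"A" * 9, "B" * 9}), "mixed", ("SIRS",))]
        ref = ClusteredReference(global_entries=[], motifs={"SIRS": ("EpA", "EpB")})
        assert match_motif(clusters, ref) == {"C0": ("EpA", "EpB")}


class TestAssignFeatures:
    def test_one_member_match_makes_cluster_common(self):
        cdr3s = ["CASSIRSSYEQYF", "CASSIRSTYEQYF", "CASSIRSAYEQYF",
                 "CASSIRSGYEQYF", "CASSIRSHYEQYF"]
        rep = make_repertoire([1] * 5, cdr3s=cdr3s, v="TRBV19*01")
        db = ReferenceDB([("TRBV19", "CASSIRSSYEQYF", "EpA")])
        cluster = TCRCluster("C0", frozenset(cdr3s), "global")
        feats = assign_antigen_features(rep, [cluster], set(), db)
        assert all(f.specificity == "common" for f in feats)
        assert all(f.cluster_status == "clustered" for f in feats)

    def test_unmatched_nonclustered_clonotype(self):
        rep = make_repertoire([1], cdr3s=["CASSWWWWWEQYF"])
        db = ReferenceDB([("TRBV19", "CASSIRSSYEQYF", "EpA")])
        feats = assign_antigen_features(rep, [], {"CASSWWWWWEQYF"}, db)
        assert feats[0].specificity == "non_common"
        assert feats[0].cluster_status == "non_clustered"

    def test_every_clonotype_covered_once(self):
        cdr3s = [f"CASS{a}GGGYEQYF" for a in "ACDEFGHIK"]
        rep = make_repertoire([1] * len(cdr3s), cdr3s=cdr3s)
        db = ReferenceDB([("TRBV19", "CASSWWWWWEQYF", "EpA")])
        cluster = TCRCluster("C0", frozenset(cdr3s[:4]), "global")
        feats = assign_antigen_features(rep, [cluster], set(cdr3s[4:]), db)
        assert sorted(f.cdr3_aa for f in feats) == sorted(cdr3s)

    def test_monotone_in_database(self):
        # enlarging the DB can only turn non_common into common
        cdr3s = [f"CASS{a}GGGYEQYF" for a in "ACDEF"]
        rep = make_repertoire([1] * 5, cdr3s=cdr3s, v="TRBV19*01")
        small = ReferenceDB([("TRBV19", cdr3s[0], "EpA")])
        large = ReferenceDB([("TRBV19", cdr3s[0], "EpA"), ("TRBV19", cdr3s[1], "EpB")])
        f_small = {f.cdr3_aa: f.specificity
                   for f in assign_antigen_features(rep, [], set(cdr3s), small)}
        f_large = {f.cdr3_aa: f.specificity
                   for f in assign_antigen_features(rep, [], set(cdr3s), large)}
        for aa in cdr3s:
            assert not (f_small[aa] == "common" and f_large[aa] == "non_common")


class TestSubsampledEvenness:
    def test_uniform_counts_give_unit_evenness(self):
        clons = [clono(f"CASS{a}WGGYEQYF") for a in "ACDEFGHIKL"]
        mean_j = subsampled_mean_evenness(clons, size=5, n_sub=20, seed=0)
        assert mean_j == pytest.approx(1.0)

    def test_full_size_equals_direct_evenness(self):
        from tcrep.diversity import pielou_evenness

        counts = [1, 2, 4, 8, 16]
        clons = [Clonotype(f"CASS{a}WGGYEQYF", "V9*01", "J1*01", c)
                 for a, c in zip("ACDEF", counts)]
        mean_j = subsampled_mean_evenness(clons, size=5, n_sub=10, seed=0)
        direct = pielou_evenness(np.array(counts) / sum(counts))
        assert mean_j == pytest.approx(direct)

    def test_seed_stability_within_monte_carlo_tolerance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 1000, size=50)
        clons = [Clonotype(f"CASS{i:03d}".replace("0", "A").replace("1", "C")
                           .replace("2", "D").replace("3", "E").replace("4", "F")
                           .replace("5", "G").replace("6", "H").replace("7", "I")
                           .replace("8", "K").replace("9", "L") + "YEQYF",
                           "V9*01", "J1*01", int(c))
                 for i, c in enumerate(counts)]
        m1 = subsampled_mean_evenness(clons, size=10, n_sub=200, seed=1)
        m2 = subsampled_mean_evenness(clons, size=10, n_sub=200, seed=2)
        # per-subsample J' sd is < 0.1 here; 3 * SE at n_sub = 200
        assert abs(m1 - m2) < 3 * 0.1 / np.sqrt(200) * 2

    def test_size_validation(self):
        clons = [clono("CASSAWGGYEQYF"), clono("CASSCWGGYEQYF")]
        with pytest.raises(DegenerateInputError):
            subsampled_mean_evenness(clons, size=3, n_sub=5, seed=0)
        with pytest.raises(DegenerateInputError):
            subsampled_mean_evenness(clons, size=1, n_sub=5, seed=0)
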