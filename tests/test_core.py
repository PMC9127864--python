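"""Clonotype tables: parsing dialects, amino-acid collapsing, frequencies."""

import pandas as pd
import pytest

from tcrep.core import (
    Clonotype,
    DegenerateInputError,
    Repertoire,
    RepertoireFormatError,
    collapse_by_cdr3aa,
    compute_frequencies,
    normalize_gene,
)
from tcrep.io import (
    read_clonotype_table,
    read_reference_db,
    write_clonotype_table,
    write_reference_db,
)


def write_airr(path, rows):
    pd.DataFrame(
        rows, columns=["duplicate_count", "junction", "junction_aa", "v_call", "j_call"]
    ).to_csv(path, sep="\t", index=False)


class TestReadClonotypeTable:
    def test_airr_read_through(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_airr(p, [
            (5, "tgtgcc", "CASSLEQYF", "TRBV9*01", "TRBJ2-1*01"),
            (3, "tgtgca", "CASSREQYF", "TRBV5-1*01", "TRBJ2-7*01"),
            (2, "tgtgcg", "CASSKEQYF", "TRBV9*01", "TRBJ2-1*01"),
        ])
        rep = read_clonotype_table(p, "airr")
        assert len(rep) == 3
        assert rep.total_count() == 10
        assert all(c.frequency is None for c in rep.clonotypes)

    def test_mixcr_hit_score_stripped(self, tmp_path):
        p = tmp_path / "s.tsv"
        pd.DataFrame(
            [(12, "tgt", "CASSLEQYF", "TRBV9*00(1200)", "TRBJ2-1*00(800),TRBJ2-7*00(500)")],
            columns=["cloneCount", "nSeqCDR3", "aaSeqCDR3",
                     "allVHitsWithScore", "allJHitsWithScore"],
        ).to_csv(p, sep="\t", index=False)
        rep = read_clonotype_table(p, "mixcr")
        assert rep.clonotypes[0].v_allele == "TRBV9*00"
        assert rep.clonotypes[0].j_allele == "TRBJ2-1*00"  # best hit kept

    def test_missing_column_names_column(self, tmp_path):
        p = tmp_path / "s.tsv"
        pd.DataFrame(
            [(5, "tgt", "TRBV9", "TRBJ2-1")],
            columns=["duplicate_count", "junction", "v_call", "j_call"],
        ).to_csv(p, sep="\t", index=False)
        with pytest.raises(RepertoireFormatError, match="junction_aa"):
            read_clonotype_table(p, "airr")

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_airr(p, [])
        with pytest.raises(RepertoireFormatError, match="no clonotype rows"):
            read_clonotype_table(p, "airr")

    def test_nonproductive_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_airr(p, [
            (5, "tgt", "CASSLEQYF", "TRBV9*01", "TRBJ2-1*01"),
            (3, "tga", "CASS*EQYF", "TRBV9*01", "TRBJ2-1*01"),
            (2, "tgg", "CASS_EQYF", "TRBV9*01", "TRBJ2-1*01"),
        ])
        rep = read_clonotype_table(p, "airr")
        assert len(rep) == 1
        assert rep.meta["n_nonproductive"] == 2

    def test_round_trip_preserves_counts_and_sequences(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_airr(p, [
            (5, "tgtgcc", "CASSLEQYF", "TRBV9*01", "TRBJ2-1*01"),
            (3, "tgtgca", "CASSREQYF", "TRBV5-1*01", "TRBJ2-7*01"),
        ])
        rep = read_clonotype_table(p, "airr", group="APA", pair_id="p0")
        q = tmp_path / "out.tsv"
        write_clonotype_table(rep, q)
        back = read_clonotype_table(q, "airr", group="APA", pair_id="p0")
        assert [(c.cdr3_aa, c.count, c.v_allele, c.j_allele) for c in back.clonotypes] == [
            (c.cdr3_aa, c.count, c.v_allele, c.j_allele) for c in rep.clonotypes
        ]


class TestCollapse:
    def rep(self, clons):
        return Repertoire("s", "APA", "p0", clons)

    def test_dominant_variant_provides_alleles(self):
        # two nt variants of one aa sequence: the higher-count variant's
        # V call becomes representative, counts accumulate
        rep = self.rep([
            Clonotype("CASSLEQYF", "TRBV9*01", "TRBJ2-1*01", 7,
                      cdr3_nt_variants=[("tgtgccagca", 7)]),
            Clonotype("CASSLEQYF", "TRBV5-1*01", "TRBJ2-7*01", 3,
                      cdr3_nt_variants=[("tgtgccagcg", 3)]),
        ])
        out = collapse_by_cdr3aa(rep)
        assert len(out) == 1
        c = out.clonotypes[0]
        assert c.count == 10
        assert c.v_allele == "TRBV9*01"

    def test_distinct_sequences_untouched(self, tiny_rep):
        out = collapse_by_cdr3aa(tiny_rep)
        assert [c.cdr3_aa for c in out.clonotypes] == [c.cdr3_aa for c in tiny_rep.clonotypes]
        assert [c.count for c in out.clonotypes] == [c.count for c in tiny_rep.clonotypes]

    def test_tie_breaks_on_smallest_nt_sequence(self):
        # equal variant counts: lexicographically smallest nt sequence wins;
        # oracle = explicit max over (count, reversed-lex) pairs
        variants = [("ttt", 5, "TRBV9*01"), ("aaa", 5, "TRBV5-1*01"), ("ggg", 5, "TRBV19*01")]
        expected = sorted(variants, key=lambda t: (-t[1], t[0]))[0][2]
        rep = self.rep([
            Clonotype("CASSLEQYF", v, "TRBJ2-1*01", n, cdr3_nt_variants=[(nt, n)])
            for nt, n, v in variants
        ])
        out = collapse_by_cdr3aa(rep)
        assert out.clonotypes[0].v_allele == expected == "TRBV5-1*01"

    def test_collapse_conserves_total_count_and_is_idempotent(self):
        rep = self.rep([
            Clonotype("CASSLEQYF", "TRBV9*01", "TRBJ2-1*01", 7,
                      cdr3_nt_variants=[("tgta", 4), ("tgtc", 3)]),
            Clonotype("CASSLEQYF", "TRBV5-1*01", "TRBJ2-1*01", 2,
                      cdr3_nt_variants=[("tgtg", 2)]),
            Clonotype("CASSREQYF", "TRBV19*01", "TRBJ2-7*01", 5,
                      cdr3_nt_variants=[("tgtt", 5)]),
        ])
        once = collapse_by_cdr3aa(rep)
        twice = collapse_by_cdr3aa(once)
        assert once.total_count() == rep.total_count() == 14
        assert [(c.cdr3_aa, c.count, c.v_allele) for c in twice.clonotypes] == [
            (c.cdr3_aa, c.count, c.v_allele) for c in once.clonotypes
        ]


class TestFrequencies:
    def test_arithmetic(self, tiny_rep):
        assert tiny_rep.frequencies() == [0.25, 0.25, 0.5]

    def test_single_clonotype(self):
        rep = compute_frequencies(
            Repertoire("s", "EH", "p0", [Clonotype("CASSLEQYF", "V", "J", 9)])
        )
        assert rep.frequencies() == [1.0]

    def test_zero_total_count_rejected(self):
        rep = Repertoire("s", "EH", "p0", [
            Clonotype("CASSLEQYF", "V", "J", 0),
            Clonotype("CASSREQYF", "V", "J", 0),
        ])
        with pytest.raises(DegenerateInputError):
            compute_frequencies(rep)


class TestReferenceDB:
    def test_normalization_and_dedup(self, tmp_path):
        p = tmp_path / "db.tsv"
        pd.DataFrame(
            [
                ("TRBV19*01", "CASSIRSSYEQYF", "EpitopeA"),
                ("TRBV19*02", "CASSIRSSYEQYF", "EpitopeA"),  # same after stripping
                ("TRBV19", "CASSIRSSYEQYF", "EpitopeB"),
            ],
            columns=["v_gene", "cdr3_aa", "epitope"],
        ).to_csv(p, sep="\t", index=False)
        db = read_reference_db(p)
        assert len(db) == 2
        assert all(v == "TRBV19" for v, _, _ in db.entries)

    def test_empty_epitope_rejected_with_count(self, tmp_path):
        p = tmp_path / "db.tsv"
        pd.DataFrame(
            [("TRBV9", "CASSLEQYF", "EpA"), ("TRBV9", "CASSREQYF", "")],
            columns=["v_gene", "cdr3_aa", "epitope"],
        ).to_csv(p, sep="\t", index=False)
        db = read_reference_db(p)
        assert len(db) == 1
        assert db.n_rejected == 1

    def test_missing_column(self, tmp_path):
        p = tmp_path / "db.tsv"
        pd.DataFrame([("TRBV9", "CASSLEQYF")], columns=["v_gene", "cdr3_aa"]).to_csv(
            p, sep="\t", index=False
        )
        with pytest.raises(RepertoireFormatError, match="epitope"):
            read_reference_db(p)

    def test_db_round_trip(self, tmp_path):
        p = tmp_path / "db.tsv"
        pd.DataFrame(
            [("TRBV9*01", "CASSLEQYF", "EpA"), ("TRBV19*01", "CASSREQYF", "EpB")],
            columns=["v_gene", "cdr3_aa", "epitope"],
        ).to_csv(p, sep="\t", index=False)
        db = read_reference_db(p)
        q = tmp_path / "out.tsv"
        write_reference_db(db, q)
        assert read_reference_db(q).entries == db.entries


@pytest.mark.parametrize(
    "call,gene",
    [("TRBV19*01", "TRBV19"), ("TRBV5-1*02", "TRBV5-1"), ("TRBV9", "TRBV9")],
)
def test_normalize_gene(call, gene):
    assert normalize_gene(call) == gene


def test_invalid_cdr3_alphabet_rejected():
    with pytest.raises(ValueError, match="non-standard"):
        Clonotype("CASS*EQYF", "V", "J", 1)
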