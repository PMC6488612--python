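"""k-mer pooling, greedy library selection, coverage and cocktail stats."""

import io

import numpy as np
import pytest

from neoorf.library import (KmerRecord, build_library, cocktail_stats,
                            coverage_curve, pool_kmers, write_library_tsv)
from neoorf.synth import make_variant
from neoorf.translate import NopRecord

from conftest import oracle_greedy


def _nop(tx1, peptide, patient="P1", entity="COAD"):
    v = make_variant(tx1, 4, "C", "", patient, entity)
    return NopRecord(variant=v, frame_label="+1", peptide=peptide,
                     protein_start=2, terminated=True)


def _rec(pep, patients):
    return KmerRecord(peptide=pep, patients=set(patients),
                      genes={"G"}, entities={"COAD"})


class TestPoolKmers:
    def test_eleven_aa_gives_two_kmers(self, tx1):
        records = pool_kmers([_nop(tx1, "ACDEFGHIKLM")], k=10)
        assert [r.peptide for r in records] == ["ACDEFGHIKL", "CDEFGHIKLM"]
        assert all(r.patients == {"P1"} for r in records)

    def test_nine_aa_contributes_nothing(self, tx1):
        assert pool_kmers([_nop(tx1, "ACDEFGHIK")], k=10) == []

    def test_same_kmer_two_variants_one_patient(self, tx1):
        nops = [_nop(tx1, "ACDEFGHIKL"), _nop(tx1, "ACDEFGHIKL")]
        (rec,) = pool_kmers(nops, k=10)
        assert rec.patients == {"P1"}


class TestBuildLibrary:
    def test_hand_example(self):
        records = [_rec("A", {"P1", "P2", "P3"}), _rec("B", {"P1", "P2"}),
                   _rec("D", {"P2", "P3"}), _rec("C", {"P4"})]
        lib = build_library(records, min_patient_count=2)
        assert [e.peptide for e in lib.entries] == ["A"]
        assert lib.covered_patients == {"P1", "P2", "P3"}

    def test_empty_records(self):
        assert build_library([], min_patient_count=2).entries == []

    def test_lexicographic_tie_break(self):
        lib = build_library([_rec("B", {"P2"}), _rec("A", {"P1"})],
                            min_patient_count=1)
        assert [e.peptide for e in lib.entries] == ["A", "B"]
        assert lib.entries[-1].cumulative_covered == 2

    def test_max_size_cap(self):
        records = [_rec("A", {"P1"}), _rec("B", {"P2"}), _rec("C", {"P3"})]
        lib = build_library(records, min_patient_count=1, max_size=2)
        assert len(lib.entries) == 2

    def test_oracle_random_instances(self):
        """Exact order/coverage match with the brute-force greedy, ties included."""
        rng = np.random.default_rng(17)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for trial in range(60):
            n_pat = int(rng.integers(2, 16))
            n_kmer = int(rng.integers(1, 31))
            records = []
            for j in range(n_kmer):
                size = int(rng.integers(1, n_pat + 1))
                pats = set(rng.choice(n_pat, size=size, replace=False).tolist())
                pep = "".join(alphabet[int(c)] for c in rng.integers(0, 20, size=10))
                records.append(_rec(pep, {f"P{p}" for p in pats}))
            # force ties: duplicate one patient set under a new peptide name
            if records and trial % 3 == 0:
                records.append(_rec("AAAAAAAAAA", set(records[0].patients)))
            for mpc in (1, 2):
                lib = build_library(records, min_patient_count=mpc)
                want = oracle_greedy(records, min_patient_count=mpc)
                got = [(e.peptide, e.newly_added_patients, e.cumulative_covered)
                       for e in lib.entries]
                assert got == want

    def test_incremental_coverage_invariants(self):
        rng = np.random.default_rng(23)
        records = [_rec(f"PEP{j:07d}",
                        {f"P{int(p)}" for p in rng.choice(40, rng.integers(1, 10),
                                                          replace=False)})
                   for j in range(50)]
        lib = build_library(records, min_patient_count=1)
        seen = set()
        last = 0
        for e in lib.entries:
            assert e.newly_added_patients and not (e.newly_added_patients & seen)
            seen |= e.newly_added_patients
            assert e.cumulative_covered == len(seen) > last
            last = e.cumulative_covered
        assert seen == lib.covered_patients

    def test_byte_identical_output_regardless_of_input_order(self, tmp_path):
        rng = np.random.default_rng(29)
        records = [_rec(f"PEP{j:07d}",
                        {f"P{int(p)}" for p in rng.choice(30, rng.integers(1, 8),
                                                          replace=False)})
                   for j in range(40)]
        shuffled = list(records)
        rng.shuffle(shuffled)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_library_tsv(build_library(records, 1), p1)
        write_library_tsv(build_library(shuffled, 1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestCoverageCurve:
    def test_single_entry(self):
        lib = build_library([_rec("A", {"P1", "P2", "P3"})], min_patient_count=2)
        assert coverage_curve(lib, 4) == [(1, 0.75)]

    def test_empty_library(self):
        assert coverage_curve(build_library([], 2), 10) == []

    def test_cumulative_points(self):
        lib = build_library([_rec("A", {"P1", "P2"}), _rec("B", {"P3"})],
                            min_patient_count=1)
        assert coverage_curve(lib, 10) == [(1, 0.2), (2, 0.3)]

    def test_too_small_cohort_errors(self):
        lib = build_library([_rec("A", {"P1", "P2", "P3"})], min_patient_count=1)
        with pytest.raises(ValueError, match="cohort_size"):
            coverage_curve(lib, 2)


class TestCocktailStats:
    def test_hand_example(self):
        records = [_rec("A", {"P1", "P2"}), _rec("B", {"P2", "P4"})]
        lib = build_library(records, min_patient_count=1)
        assert cocktail_stats(lib, records) == pytest.approx(1 / 3)

    def test_single_peptide_library_is_zero(self):
        records = [_rec("A", {"P1", "P2"})]
        lib = build_library(records, min_patient_count=1)
        assert cocktail_stats(lib, records) == 0.0

    def test_all_patients_share_both_is_one(self):
        # upper bound of the statistic: every covered patient carries both
        from neoorf.library import LibraryEntry, PeptideLibrary

        records = [_rec("A", {"P1", "P2"}), _rec("B", {"P1", "P2"})]
        lib = PeptideLibrary(
            entries=[
                LibraryEntry("A", 2, frozenset({"P1"}), 1, frozenset({"G"})),
                LibraryEntry("B", 2, frozenset({"P2"}), 2, frozenset({"G"})),
            ],
            k=10, min_patient_count=1,
        )
        assert cocktail_stats(lib, records) == 1.0

    def test_empty_library_undefined(self):
        assert cocktail_stats(build_library([], 2), []) is None

    def test_membership_not_greedy_attribution(self):
        # P2 is newly added by A but also belongs to B: counts twice
        records = [_rec("A", {"P1", "P2"}), _rec("B", {"P2", "P3"})]
        lib = build_library(records, min_patient_count=1)
        assert cocktail_stats(lib, records) == pytest.approx(1 / 3)
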