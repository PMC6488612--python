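"""Transcript/variant/expression I/O and coordinate mapping."""

import numpy as np
import pandas as pd
import pytest

from neoorf.models import (Cohort, TranscriptModel, load_expression,
                           load_transcripts, load_variants, write_variants)
from neoorf.synth import SynthSpec, generate_bundle, make_transcriptome


def _write_tx_files(tmp_path, rows, seqs):
    fasta = tmp_path / "t.fasta"
    fasta.write_text("".join(f">{tid}\n{seq}\n" for tid, seq in seqs.items()))
    tsv = tmp_path / "t.tsv"
    header = "transcript_id\tgene_symbol\tcontig\tstrand\texon_starts\texon_ends\tcds_start\tcds_end\n"
    tsv.write_text(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return fasta, tsv


class TestLoadTranscripts:
    def test_single_plus_strand(self, tmp_path):
        fasta, tsv = _write_tx_files(
            tmp_path,
            rows=[("TX1", "G1", "chr1", "+", "1001", "1015", 0, 15)],
            seqs={"TX1": "ATGGCAGATTGGTAA"},
        )
        (model,) = load_transcripts(fasta, tsv)
        assert model.protein == "MADW"
        assert model.cds_sequence == "ATGGCAGATTGGTAA"

    def test_minus_strand_reverse_complemented(self, tmp_path):
        # FASTA carries forward genomic strand; mRNA is its reverse complement
        fasta, tsv = _write_tx_files(
            tmp_path,
            rows=[("TX2", "G2", "chr1", "-", "1001", "1015", 0, 15)],
            seqs={"TX2": "TTACCAATCTGCCAT"},
        )
        (model,) = load_transcripts(fasta, tsv)
        assert model.mrna_sequence == "ATGGCAGATTGGTAA"
        assert model.protein == "MADW"

    def test_empty_model_table(self, tmp_path):
        fasta, tsv = _write_tx_files(tmp_path, rows=[], seqs={})
        assert load_transcripts(fasta, tsv) == []

    def test_exon_length_mismatch_errors(self, tmp_path):
        fasta, tsv = _write_tx_files(
            tmp_path,
            rows=[("TX1", "G1", "chr1", "+", "1001", "1010", 0, 9)],
            seqs={"TX1": "ATGGCAGATTGGTAA"},
        )
        with pytest.raises(ValueError, match="exon lengths"):
            load_transcripts(fasta, tsv)

    def test_missing_sequence_errors(self, tmp_path):
        fasta, tsv = _write_tx_files(
            tmp_path,
            rows=[("TXMISSING", "G1", "chr1", "+", "1001", "1015", 0, 15)],
            seqs={"TX1": "ATGGCAGATTGGTAA"},
        )
        with pytest.raises(ValueError, match="TXMISSING"):
            load_transcripts(fasta, tsv)

    def test_cds_not_multiple_of_three_errors(self, tmp_path):
        fasta, tsv = _write_tx_files(
            tmp_path,
            rows=[("TX1", "G1", "chr1", "+", "1001", "1015", 0, 14)],
            seqs={"TX1": "ATGGCAGATTGGTAA"},
        )
        with pytest.raises(ValueError, match="multiple of 3"):
            load_transcripts(fasta, tsv)


class TestCoordinateMapping:
    def test_plus_strand_offset(self, tx1):
        assert tx1.map_genomic_to_mrna(1005) == 4

    def test_minus_strand_offset(self, tx1_minus):
        assert tx1_minus.map_genomic_to_mrna(1015) == 0
        assert tx1_minus.map_genomic_to_mrna(1001) == 14

    def test_intronic_position_errors(self, tx1):
        with pytest.raises(ValueError, match="not exonic"):
            tx1.map_genomic_to_mrna(999)

    def test_bijection_both_strands(self, transcriptome):
        """Exhaustive: every exonic base maps to a unique offset and back."""
        for t in transcriptome[:6]:
            offsets = []
            for s, e in sorted(t.exons):
                for pos in range(s, e + 1):
                    off = t.map_genomic_to_mrna(pos)
                    assert t.map_mrna_to_genomic(off) == pos
                    offsets.append(off)
            assert sorted(offsets) == list(range(len(t.mrna_sequence)))


class TestLoadVariants:
    HEADER = "patient_id\tentity\tgene_symbol\ttranscript_id\tgenomic_pos\tref\talt\n"

    def _load(self, tmp_path, tx, rows):
        path = tmp_path / "v.tsv"
        path.write_text(self.HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
        return load_variants(path, [tx])

    def test_one_bp_deletion_kept(self, tmp_path, tx1):
        cohort = self._load(tmp_path, tx1, [("P1", "COAD", "G1", "TX1", 1005, "C", "-")])
        (v,) = cohort.variants
        assert v.net_shift_d == -1
        assert v.mrna_offset == 4

    def test_inframe_deletion_dropped(self, tmp_path, tx1):
        cohort = self._load(tmp_path, tx1, [("P1", "COAD", "G1", "TX1", 1005, "CAG", "-")])
        assert cohort.variants == []
        assert cohort.n_patients == 1  # patient still counted in the cohort

    def test_empty_file(self, tmp_path, tx1):
        cohort = self._load(tmp_path, tx1, [])
        assert cohort.n_patients == 0 and cohort.variants == []

    def test_unknown_transcript_warn_vs_error(self, tmp_path, tx1):
        rows = [("P1", "COAD", "GX", "TXUNKNOWN", 1005, "C", "-")]
        cohort = self._load(tmp_path, tx1, rows)
        assert cohort.variants == []
        path = tmp_path / "v.tsv"
        with pytest.raises(ValueError, match="unknown transcript"):
            load_variants(path, [tx1], on_unknown_transcript="error")

    def test_canonical_transcript_fallback(self, tmp_path, tx1):
        # empty transcript_id resolves to the gene's longest CDS
        cohort = self._load(tmp_path, tx1, [("P1", "COAD", "G1", "", 1005, "C", "-")])
        assert cohort.variants[0].transcript_id == "TX1"

    def test_minus_strand_alleles_reverse_complemented(self, tmp_path, tx1_minus):
        # genomic G at 1011 is mRNA C at offset 4 (revcomp orientation)
        cohort = self._load(
            tmp_path, tx1_minus,
            [("P1", "COAD", "G1M", "TX1M", 1011, "G", "-")],
        )
        (v,) = cohort.variants
        assert v.mrna_offset == 4
        assert v.mrna_ref == "C"


class TestRoundTrip:
    def test_cohort_serialization_roundtrip(self, tmp_path):
        """Writing and reloading a cohort reproduces all derived fields."""
        from neoorf.synth import plant_cohort

        spec = SynthSpec(seed=5)
        models = make_transcriptome(spec)
        cohort, _, extra = plant_cohort(spec, models)
        path = tmp_path / "variants.tsv"
        write_variants(cohort, path)
        reloaded = load_variants(path, models + extra)
        key = lambda v: (v.patient_id, v.transcript_id, v.mrna_offset, v.mrna_ref, v.mrna_alt)
        orig = sorted(map(key, cohort.variants))
        back = sorted(map(key, reloaded.variants))
        assert orig == back
        assert {v.net_shift_d for v in reloaded.variants} == \
               {v.net_shift_d for v in cohort.variants}


class TestExpression:
    def _write(self, tmp_path, rows):
        path = tmp_path / "e.tsv"
        path.write_text("gene\tentity\tmean_log2\n" +
                        "".join("\t".join(map(str, r)) + "\n" for r in rows))
        return path

    def test_round_trip_lookup(self, tmp_path):
        table = load_expression(self._write(tmp_path, [("TP53", "COAD", 7.3)]))
        assert table.lookup("TP53", "COAD") == 7.3

    def test_absent_pair_is_none(self, tmp_path):
        table = load_expression(self._write(tmp_path, [("TP53", "COAD", 7.3)]))
        assert table.lookup("TP53", "UCEC") is None

    def test_duplicate_pair_errors(self, tmp_path):
        path = self._write(tmp_path, [("TP53", "COAD", 7.3), ("TP53", "COAD", 2.0)])
        with pytest.raises(ValueError, match="duplicate"):
            load_expression(path)

    def test_non_numeric_errors(self, tmp_path):
        path = self._write(tmp_path, [("TP53", "COAD", "high")])
        with pytest.raises(ValueError, match="non-numeric"):
            load_expression(path)


class TestCohortInvariants:
    def test_patient_with_two_entities_rejected(self):
        with pytest.raises(ValueError, match="two entities"):
            Cohort(patients={("P1", "COAD"), ("P1", "UCEC")})

    def test_variant_patient_must_be_registered(self, tx1):
        from neoorf.synth import make_variant

        v = make_variant(tx1, 4, "C", "", "P9", "COAD")
        with pytest.raises(ValueError, match="not in cohort"):
            Cohort(patients={("P1", "COAD")}, variants=[v])
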