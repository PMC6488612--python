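"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately take a different route from the package:
whole-string Biopython translation plus plain string slicing/splitting,
against the package's codon-by-codon scanners.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from neoorf.models import TranscriptModel
from neoorf.synth import SynthSpec, make_transcriptome, make_variant


@pytest.fixture
def tx1() -> TranscriptModel:
    """Tiny plus-strand transcript: protein MADW, one exon at 1001-1015."""
    return TranscriptModel(
        transcript_id="TX1", gene_symbol="G1", contig="chr1", strand="+",
        mrna_sequence="ATGGCAGATTGGTAA", cds_start=0, cds_end=15,
        exons=((1001, 1015),),
    )


@pytest.fixture
def tx1_minus() -> TranscriptModel:
    """Same mRNA content on the minus strand of 1001-1015."""
    return TranscriptModel(
        transcript_id="TX1M", gene_symbol="G1M", contig="chr1", strand="-",
        mrna_sequence="ATGGCAGATTGGTAA", cds_start=0, cds_end=15,
        exons=((1001, 1015),),
    )


@pytest.fixture(scope="session")
def transcriptome():
    """A deterministic 30-transcript synthetic transcriptome."""
    return make_transcriptome(SynthSpec(seed=42))


def random_frameshift(rng, t: TranscriptModel, patient="P0", entity="COAD"):
    """Uniform random 1-2 bp deletion or insertion inside the CDS.

    Insertions need a 5' anchor base, so their offset starts at 1.
    """
    kind = int(rng.integers(0, 4))
    ln = 1 + kind // 2
    lo = t.cds_start if kind % 2 == 0 else max(t.cds_start, 1)
    x = int(rng.integers(lo, t.cds_end - 3 - ln))
    if kind % 2 == 0:
        return make_variant(t, x, t.mrna_sequence[x : x + ln], "", patient, entity)
    ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=ln))
    return make_variant(t, x, "", ins, patient, entity)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_nop(t: TranscriptModel, v) -> tuple[str, int, bool]:
    """Mutate-and-translate reference oracle: (peptide, protein_start, terminated)."""
    seq = t.mrna_sequence
    mutated = seq[: v.mrna_offset] + v.mrna_alt + seq[v.mrna_offset + len(v.mrna_ref):]
    window = mutated[t.cds_start:]
    window = window[: len(window) // 3 * 3]
    protein = str(Seq(window).translate())
    j = (v.mrna_offset - t.cds_start) // 3
    tail = protein[j:]
    at = tail.find("*")
    if at < 0:
        return tail, j + 1, False
    return tail[:at], j + 1, True


def oracle_pnops(t: TranscriptModel, min_len: int = 10) -> set[tuple]:
    """Shifted-translate / split-on-stop / length-filter reference oracle."""
    out: set[tuple] = set()
    for label, shift in (("+1", 1), ("-1", 2)):
        start = t.cds_start + shift
        sub = t.mrna_sequence[start:]
        sub = sub[: len(sub) // 3 * 3]
        protein = str(Seq(sub).translate())
        segments = protein.split("*")
        cum = 0
        for i, seg in enumerate(segments):
            terminated = i < len(segments) - 1
            if len(seg) >= min_len:
                out.add((t.transcript_id, label, start + 3 * cum, seg, terminated))
            cum += len(seg) + 1
    return out


def oracle_greedy(records, min_patient_count=2, max_size=None):
    """Sort / scan / accept-if-new greedy rule, reimplemented bluntly.

    Returns [(peptide, newly_added frozenset, cumulative_covered)].
    """
    pool = [r for r in records if len(r.patients) >= min_patient_count]
    pool = sorted(pool, key=lambda r: (-len(r.patients), r.peptide))
    covered: set = set()
    out = []
    for r in pool:
        if max_size is not None and len(out) >= max_size:
            break
        new = set(r.patients) - covered
        if new:
            covered = covered | new
            out.append((r.peptide, frozenset(new), len(covered)))
    return out
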