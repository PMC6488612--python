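"""Translate frameshift variants in their shifted frame up to the first stop.

A frameshift indel moves downstream translation into one of the two
alternative reading frames. The neo open reading frame peptide (NOP) is the
translation of the mutant mRNA, starting at the codon that contains the
first changed base, continuing — through the annotated 3'UTR if necessary —
until the first stop codon in the shifted frame. The annotated in-frame stop
does not terminate a shifted frame.

Frame labels: a net shift ``d`` with ``d % 3 == 2`` (e.g. a 1-bp deletion)
reads downstream reference bases at offsets congruent to +1 relative to the
annotated frame and is labelled ``"+1"``; ``d % 3 == 1`` (e.g. a 1-bp
insertion) is labelled ``"-1"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from ._codon import translate_until_stop
from .models import FrameshiftVariant, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "NopRecord",
    "classify_frame",
    "mutate_mrna",
    "translate_nop",
    "write_nop_table",
    "write_nop_fasta",
]


@dataclass(frozen=True)
class NopRecord:
    """A translated neo-peptide: variant, frame class, peptide, start, flag.

    ``protein_start`` is the 1-based codon index (in the reference protein)
    of the codon containing the first changed base; ``terminated`` is False
    when the shifted frame reached the transcript 3' end without a stop.
    """

    variant: FrameshiftVariant
    frame_label: str
    peptide: str
    protein_start: int
    terminated: bool
    junction_len: int = 1

    @property
    def post_junction_suffix(self) -> str:
        """Peptide minus the leading residues whose codons overlap the edit.

        For 1-bp indels this is the peptide minus its first residue; a
        multi-base insertion can spill into the following codon, in which
        case that residue is trimmed too. Only this suffix is pure
        shifted-frame reference sequence (and hence findable in a pNOP).
        """
        return self.peptide[self.junction_len :]

    def __post_init__(self):
        if "*" in self.peptide:
            raise ValueError("NOP peptide contains a stop symbol")
        if self.protein_start < 1:
            raise ValueError("protein_start must be >= 1")


def classify_frame(v: FrameshiftVariant) -> str:
    """Return ``"+1"`` or ``"-1"`` for a valid frameshift."""
    r = v.net_shift_d % 3
    if r == 0:
        raise ValueError("not a frameshift: net shift is a multiple of 3")
    return "+1" if r == 2 else "-1"


def mutate_mrna(t: TranscriptModel, v: FrameshiftVariant) -> str:
    """Apply the variant's edit to the transcript's mRNA sequence."""
    seq = t.mrna_sequence
    ref = v.mrna_ref
    if ref and seq[v.mrna_offset : v.mrna_offset + len(ref)] != ref:
        raise ValueError(
            f"reference mismatch at {t.transcript_id} offset {v.mrna_offset}: "
            f"expected {ref!r}, sequence has "
            f"{seq[v.mrna_offset : v.mrna_offset + len(ref)]!r}"
        )
    mutated = seq[: v.mrna_offset] + v.mrna_alt + seq[v.mrna_offset + len(ref):]
    assert len(mutated) - len(seq) == v.net_shift_d
    return mutated


def translate_nop(t: TranscriptModel, v: FrameshiftVariant) -> NopRecord:
    """Translate one frameshift variant into its NOP.

    Translation runs in the annotated frame from ``cds_start`` over the
    *mutant* sequence; the NOP is the suffix from the junction codon (the
    codon containing the first changed base) to the first stop thereafter,
    stop excluded.
    """
    mutated = mutate_mrna(t, v)
    junction = (v.mrna_offset - t.cds_start) // 3
    start_nt = t.cds_start + 3 * junction
    peptide, terminated = translate_until_stop(mutated, start_nt)
    if v.mrna_alt:
        # last codon (in mutated coordinates) touched by inserted bases
        last = (v.mrna_offset + len(v.mrna_alt) - 1 - t.cds_start) // 3
    else:
        last = junction
    return NopRecord(
        variant=v,
        frame_label=classify_frame(v),
        peptide=peptide,
        protein_start=junction + 1,
        terminated=terminated,
        junction_len=last - junction + 1,
    )


def translate_cohort(transcripts: Iterable[TranscriptModel], variants) -> list[NopRecord]:
    """Translate every variant against its transcript model."""
    by_id = {t.transcript_id: t for t in transcripts}
    return [translate_nop(by_id[v.transcript_id], v) for v in variants]


def write_nop_table(nops: Iterable[NopRecord], path) -> None:
    """TSV export: one row per NOP."""
    import pandas as pd

    rows = [
        (n.variant.patient_id, n.variant.entity, n.variant.gene_symbol,
         n.variant.transcript_id, n.protein_start, n.frame_label, n.peptide,
         n.terminated)
        for n in nops
    ]
    pd.DataFrame(
        rows,
        columns=["patient_id", "entity", "gene", "transcript", "protein_start",
                 "frame", "peptide", "terminated"],
    ).to_csv(path, sep="\t", index=False)


def write_nop_fasta(nops: Iterable[NopRecord], path) -> None:
    with open(path, "w") as fh:
        for n in nops:
            if not n.peptide:
                continue
            v = n.variant
            fh.write(
                f">{v.patient_id}|{v.transcript_id}|p{n.protein_start}"
                f"|{n.frame_label}\n{n.peptide}\n"
            )
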