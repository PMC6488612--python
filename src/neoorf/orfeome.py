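"""Proto-NOP enumeration, the Neo-ORFeome, and the in-frame ORFeome index.

A proto-NOP (pNOP) is a maximal stop-free peptide segment, at least
``min_len`` residues long, read from a transcript in one of the two shifted
frames (+1 or -1) from the first full codon of that frame at/after the CDS
start through the transcript 3' end. Any simple frameshift falling in the
region upstream of a pNOP converges onto it: the pNOP is the template the
mutant translation runs along. The union of all pNOPs over a transcriptome
is the Neo-ORFeome.

The ORFeome index is the complementary structure for the *annotated* frame:
the set of all length-k peptide windows of every reference protein, used to
exclude candidate neo-peptides that also occur in the normal proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from ._codon import STOP_CODONS, translate_codon
from .models import TranscriptModel
from .translate import NopRecord

__all__ = [
    "PnopRecord",
    "OrfeomeIndex",
    "enumerate_pnops",
    "neo_orfeome_size",
    "build_orfeome_index",
    "map_nop_to_pnop",
    "write_pnop_fasta",
]


@dataclass(frozen=True)
class PnopRecord:
    """One maximal stop-free shifted-frame segment of a transcript.

    ``start_offset`` is the 0-based mRNA offset of the segment's first codon;
    ``terminated`` is False for a segment cut by the transcript 3' end rather
    than a stop codon.
    """

    transcript_id: str
    frame_label: str
    start_offset: int
    peptide: str
    terminated: bool

    def __post_init__(self):
        if "*" in self.peptide:
            raise ValueError("pNOP peptide contains a stop symbol")


_FRAME_SHIFT = {"+1": 1, "-1": 2}


def enumerate_pnops(
    t: TranscriptModel,
    min_len: int = 10,
    include_utr: bool = True,
) -> list[PnopRecord]:
    """Enumerate both shifted frames of one transcript.

    The "+1" frame starts at ``cds_start + 1``, the "-1" frame at
    ``cds_start + 2``; translation runs to the transcript 3' end (or to
    ``cds_end`` when ``include_utr`` is False), is split at stop codons, and
    stop-free segments of at least ``min_len`` residues are kept. A trailing
    segment cut by the sequence end is kept and flagged unterminated.
    """
    seq = t.mrna_sequence
    end = len(seq) if include_utr else t.cds_end
    out: list[PnopRecord] = []
    for label, shift in _FRAME_SHIFT.items():
        start = t.cds_start + shift
        seg: list[str] = []
        seg_start = start
        pos = start
        while pos + 3 <= end:
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if len(seg) >= min_len:
                    out.append(
                        PnopRecord(t.transcript_id, label, seg_start, "".join(seg), True)
                    )
                seg = []
                seg_start = pos + 3
            else:
                seg.append(translate_codon(codon))
            pos += 3
        if len(seg) >= min_len:
            out.append(
                PnopRecord(t.transcript_id, label, seg_start, "".join(seg), False)
            )
    return out


def neo_orfeome_size(pnops: Iterable[PnopRecord]) -> tuple[int, int]:
    """Total Neo-ORFeome size as (amino acids, nucleotides)."""
    total_aa = sum(len(p.peptide) for p in pnops)
    return total_aa, 3 * total_aa


class OrfeomeIndex:
    """Exact-match set of all k-mers tiled from the reference proteome.

    Peptide windows containing ``X`` (from ambiguous codons) are never
    indexed and never match a query.
    """

    def __init__(self, k: int, members: set[str] = ()):
        self.k = int(k)
        self.members: set[str] = set(members)
        for m in self.members:
            if len(m) != self.k:
                raise ValueError(f"index member {m!r} is not a {self.k}-mer")

    def __contains__(self, kmer: str) -> bool:
        if "X" in kmer:
            return False
        return kmer in self.members

    def __len__(self):
        return len(self.members)

    def add_protein(self, protein: str) -> None:
        k = self.k
        for i in range(len(protein) - k + 1):
            window = protein[i : i + k]
            if "X" not in window:
                self.members.add(window)

    def to_text(self, path) -> None:
        """Sorted one-kmer-per-line serialization (bit-exact diffable)."""
        with open(path, "w") as fh:
            for kmer in sorted(self.members):
                fh.write(kmer + "\n")

    @classmethod
    def from_text(cls, path, k: Optional[int] = None) -> "OrfeomeIndex":
        with open(path) as fh:
            members = {line.strip() for line in fh if line.strip()}
        if k is None:
            if not members:
                raise ValueError("cannot infer k from an empty index file")
            k = len(next(iter(members)))
        return cls(k, members)


def build_orfeome_index(transcripts: Iterable[TranscriptModel], k: int = 10) -> OrfeomeIndex:
    """Tile every reference in-frame protein (stop excluded) into k-mers."""
    idx = OrfeomeIndex(k)
    for t in transcripts:
        idx.add_protein(t.protein)
    return idx


def map_nop_to_pnop(
    nop: NopRecord, pnops: Iterable[PnopRecord]
) -> Optional[tuple[PnopRecord, int]]:
    """Locate a NOP's post-junction suffix inside its transcript's pNOPs.

    The junction residue(s) sit in codons that mix reference and edited
    bases, so only the pure shifted-frame suffix
    (:attr:`NopRecord.post_junction_suffix`) is matched. Returns the matching
    same-frame pNOP and the amino-acid offset of the suffix within it, or
    None when the suffix is empty or not retained (e.g. below the pNOP
    length threshold). A short suffix can occur in several same-frame pNOPs
    by chance; the true template is then the segment whose mRNA interval
    contains the point where reference sequence resumes after the edit
    (same-frame segments are disjoint, so this is unique). Residual
    ambiguity violates the pNOP invariants and raises.
    """
    suffix = nop.post_junction_suffix
    if not suffix:
        return None
    hits = []
    for p in pnops:
        if p.frame_label != nop.frame_label:
            continue
        at = p.peptide.find(suffix)
        if at >= 0:
            hits.append((p, at))
    if len(hits) > 1:
        v = nop.variant
        resume = v.mrna_offset + len(v.mrna_ref)
        hits = [
            (p, at) for p, at in hits
            if p.start_offset <= resume < p.start_offset + 3 * len(p.peptide) + 3
        ]
    if len(hits) > 1:
        raise ValueError(
            f"NOP suffix {suffix[:12]!r}... contained in {len(hits)} same-frame "
            "pNOPs — corrupt pNOP set"
        )
    return hits[0] if hits else None


def write_pnop_fasta(pnops: Iterable[PnopRecord], path) -> None:
    with open(path, "w") as fh:
        for p in pnops:
            fh.write(f">{p.transcript_id}|{p.frame_label}|{p.start_offset}\n{p.peptide}\n")
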