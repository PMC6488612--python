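"""Data model and file I/O for transcripts, frameshift cohorts and expression.

Coordinate conventions
----------------------
Genomic positions are 1-based inclusive (MAF style); all mRNA/CDS offsets are
0-based half-open. Minus-strand transcripts are reverse-complemented once at
load time, so every downstream module works purely in mRNA space.

File dialects
-------------
* Transcript sequences: FASTA keyed by transcript_id, holding the spliced
  transcript on the *forward genomic strand* (exons concatenated in ascending
  genomic order). Minus-strand entries are reverse-complemented at load.
* Transcript models: TSV with columns ``transcript_id, gene_symbol, contig,
  strand, exon_starts, exon_ends, cds_start, cds_end``. ``exon_starts`` /
  ``exon_ends`` are comma lists of 1-based inclusive genomic coordinates in
  ascending genomic order; ``cds_start`` / ``cds_end`` are 0-based mRNA
  offsets (half-open window that includes the stop codon).
* Variants: TSV with columns ``patient_id, entity, gene_symbol,
  transcript_id, genomic_pos, ref, alt``. Deletions encode ``alt`` as ``-``
  and ``genomic_pos`` as the first deleted base; insertions encode ``ref`` as
  ``-`` and ``genomic_pos`` as the base 5' of the insertion point on the
  forward genomic strand.
* Expression: TSV with columns ``gene, entity, mean_log2``.

All readers tolerate gzip (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from ._codon import translate_until_stop

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "FrameshiftVariant",
    "ExpressionTable",
    "Cohort",
    "load_transcripts",
    "load_variants",
    "load_expression",
    "write_variants",
]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript anchored on the genome: mRNA sequence + CDS + exon map.

    ``mrna_sequence`` is 5'->3' in mRNA orientation; ``exons`` are 1-based
    inclusive genomic intervals listed in transcript order (descending
    genomic coordinate for minus-strand transcripts).
    """

    transcript_id: str
    gene_symbol: str
    contig: str
    strand: str
    mrna_sequence: str
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_end - self.cds_start} "
                "is not a multiple of 3"
            )
        if self.cds_end > len(self.mrna_sequence):
            raise ValueError(f"{self.transcript_id}: cds_end beyond sequence end")
        exon_len = sum(e - s + 1 for s, e in self.exons)
        if exon_len != len(self.mrna_sequence):
            raise ValueError(
                f"{self.transcript_id}: exon lengths sum to {exon_len}, "
                f"sequence length is {len(self.mrna_sequence)}"
            )
        spans = sorted((min(s, e), max(s, e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def cds_sequence(self) -> str:
        return self.mrna_sequence[self.cds_start : self.cds_end]

    @property
    def protein(self) -> str:
        """Frame-0 CDS translation, trailing stop stripped."""
        aa = str(Seq(self.cds_sequence).translate())
        return aa.rstrip("*")

    def check_start_codon(self, strict: bool = False) -> bool:
        ok = self.protein[:1] == "M"
        if not ok:
            msg = f"{self.transcript_id}: CDS translation does not begin with M"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
        return ok

    # ---- coordinate maps ------------------------------------------------

    def map_genomic_to_mrna(self, genomic_pos: int) -> int:
        """1-based genomic position -> 0-based mRNA offset.

        Raises ``ValueError('not exonic: ...')`` for intronic or out-of-range
        positions.
        """
        cum = 0
        for s, e in self.exons:
            if s <= genomic_pos <= e:
                if self.strand == "+":
                    return cum + (genomic_pos - s)
                return cum + (e - genomic_pos)
            cum += e - s + 1
        raise ValueError(
            f"not exonic: {self.contig}:{genomic_pos} on {self.transcript_id}"
        )

    def map_mrna_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`map_genomic_to_mrna`."""
        if not 0 <= offset < len(self.mrna_sequence):
            raise ValueError(f"mRNA offset {offset} outside transcript")
        cum = 0
        for s, e in self.exons:
            width = e - s + 1
            if offset < cum + width:
                within = offset - cum
                if self.strand == "+":
                    return s + within
                return e - within
            cum += width
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class FrameshiftVariant:
    """One patient's frameshift indel with derived mRNA-space fields.

    ``ref_allele``/``alt_allele`` are the input (forward genomic strand,
    ``-`` for empty) alleles; ``mrna_ref``/``mrna_alt`` are the same edit in
    mRNA orientation with empty strings for absent alleles. ``mrna_offset``
    is the 0-based mRNA offset of the first changed base.
    """

    patient_id: str
    entity: str
    gene_symbol: str
    transcript_id: str
    genomic_pos: int
    ref_allele: str
    alt_allele: str
    mrna_offset: int
    net_shift_d: int
    mrna_ref: str = ""
    mrna_alt: str = ""

    def __post_init__(self):
        if self.net_shift_d % 3 == 0:
            raise ValueError(
                f"{self.patient_id}/{self.transcript_id}: net shift "
                f"{self.net_shift_d} is a multiple of 3 — not a frameshift"
            )

    @property
    def site_key(self) -> tuple:
        """Identity of the event (recurrence grouping key)."""
        return (self.transcript_id, self.mrna_offset, self.mrna_ref, self.mrna_alt)


class ExpressionTable:
    """(gene, entity) -> mean log2 expression; absent pairs are queryable."""

    def __init__(self, values: dict[tuple[str, str], float]):
        for (g, ent), v in values.items():
            if not pd.notna(v) or v in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite expression for ({g}, {ent})")
        self._values = dict(values)

    def lookup(self, gene: str, entity: str) -> Optional[float]:
        return self._values.get((gene, entity))

    def __len__(self):
        return len(self._values)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._values

    def to_tsv(self, path) -> None:
        rows = sorted((g, e, v) for (g, e), v in self._values.items())
        df = pd.DataFrame(rows, columns=["gene", "entity", "mean_log2"])
        df.to_csv(path, sep="\t", index=False)


@dataclass
class Cohort:
    """Patients (with a single tumor entity each) and their frameshifts."""

    patients: set[tuple[str, str]]
    variants: list[FrameshiftVariant] = field(default_factory=list)

    def __post_init__(self):
        by_id: dict[str, str] = {}
        for pid, ent in self.patients:
            if pid in by_id and by_id[pid] != ent:
                raise ValueError(f"patient {pid} assigned to two entities")
            by_id[pid] = ent
        for v in self.variants:
            if (v.patient_id, v.entity) not in self.patients:
                raise ValueError(f"variant patient {v.patient_id} not in cohort")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patients_of_entity(self, entity: str) -> set[str]:
        if entity == "ALL":
            return {pid for pid, _ in self.patients}
        return {pid for pid, ent in self.patients if ent == entity}

    @property
    def entities(self) -> set[str]:
        return {ent for _, ent in self.patients}


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def load_transcripts(fasta_path, model_path, strict_start: bool = False) -> list[TranscriptModel]:
    """Read transcript models from a FASTA + model TSV pair.

    The FASTA holds forward-genomic-strand spliced sequences; minus-strand
    transcripts are reverse-complemented here so that ``mrna_sequence`` is in
    mRNA orientation for every model.
    """
    with _open_text(fasta_path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    table = pd.read_csv(model_path, sep="\t", dtype=str)
    models: list[TranscriptModel] = []
    for _, row in table.iterrows():
        tid = row["transcript_id"]
        if tid not in seqs:
            raise ValueError(f"no FASTA sequence for transcript {tid}")
        strand = row["strand"]
        seq = seqs[tid]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        starts = [int(x) for x in str(row["exon_starts"]).split(",") if x]
        ends = [int(x) for x in str(row["exon_ends"]).split(",") if x]
        if len(starts) != len(ends):
            raise ValueError(f"{tid}: exon_starts/exon_ends length mismatch")
        exons = sorted(zip(starts, ends))
        if strand == "-":
            exons = exons[::-1]
        model = TranscriptModel(
            transcript_id=tid,
            gene_symbol=row["gene_symbol"],
            contig=row["contig"],
            strand=strand,
            mrna_sequence=seq,
            cds_start=int(row["cds_start"]),
            cds_end=int(row["cds_end"]),
            exons=tuple(tuple(x) for x in exons),
        )
        model.check_start_codon(strict=strict_start)
        models.append(model)
    return models


def _resolve_edit(t: TranscriptModel, genomic_pos: int, ref: str, alt: str):
    """Place a MAF-style edit into mRNA space.

    Returns ``(mrna_offset, mrna_ref, mrna_alt)``. Deletion alleles cover
    ``genomic_pos .. genomic_pos+len(ref)-1`` on the forward strand;
    insertions go between ``genomic_pos`` and ``genomic_pos+1``.
    """
    ref = "" if ref in ("-", "", None) else ref.upper()
    alt = "" if alt in ("-", "", None) else alt.upper()
    if ref:  # deletion or block substitution anchored at first ref base
        if t.strand == "+":
            off = t.map_genomic_to_mrna(genomic_pos)
            return off, ref, alt
        off = t.map_genomic_to_mrna(genomic_pos + len(ref) - 1)
        rc = lambda s: str(Seq(s).reverse_complement()) if s else ""
        return off, rc(ref), rc(alt)
    # pure insertion
    if t.strand == "+":
        off = t.map_genomic_to_mrna(genomic_pos) + 1
        return off, "", alt
    off = t.map_genomic_to_mrna(genomic_pos)
    return off, "", str(Seq(alt).reverse_complement())


def load_variants(
    maf_like_path,
    transcripts: Iterable[TranscriptModel],
    on_unknown_transcript: str = "warn",
) -> Cohort:
    """Read a MAF-subset variant TSV into a :class:`Cohort`.

    Rows are dropped (with logged counts) when the indel is in-frame, when
    the position is not exonic, or when the first changed base falls outside
    the CDS window. Unknown transcript ids drop the row with a warning, or
    raise when ``on_unknown_transcript='error'``. Rows with an empty
    ``transcript_id`` are assigned the gene's canonical transcript (longest
    CDS).
    """
    by_id = {t.transcript_id: t for t in transcripts}
    canonical: dict[str, TranscriptModel] = {}
    for t in by_id.values():
        cur = canonical.get(t.gene_symbol)
        if cur is None or (t.cds_end - t.cds_start) > (cur.cds_end - cur.cds_start):
            canonical[t.gene_symbol] = t

    df = pd.read_csv(maf_like_path, sep="\t", dtype=str, keep_default_na=False)
    patients: set[tuple[str, str]] = set()
    variants: list[FrameshiftVariant] = []
    n_inframe = n_outside_cds = n_unknown = n_not_exonic = 0
    for idx, row in df.iterrows():
        patients.add((row["patient_id"], row["entity"]))
        ref = row["ref"] if row["ref"] not in ("-", "") else ""
        alt = row["alt"] if row["alt"] not in ("-", "") else ""
        d = len(alt) - len(ref)
        if d % 3 == 0:
            n_inframe += 1
            continue
        tid = row.get("transcript_id", "")
        if tid:
            t = by_id.get(tid)
        else:
            t = canonical.get(row["gene_symbol"])
        if t is None:
            if on_unknown_transcript == "error":
                raise ValueError(f"row {idx}: unknown transcript {tid!r}")
            logger.warning("row %d: unknown transcript %r, dropped", idx, tid)
            n_unknown += 1
            continue
        try:
            off, mrna_ref, mrna_alt = _resolve_edit(
                t, int(row["genomic_pos"]), row["ref"], row["alt"]
            )
        except ValueError:
            n_not_exonic += 1
            continue
        if not t.cds_start <= off < t.cds_end:
            n_outside_cds += 1
            continue
        variants.append(
            FrameshiftVariant(
                patient_id=row["patient_id"],
                entity=row["entity"],
                gene_symbol=t.gene_symbol,
                transcript_id=t.transcript_id,
                genomic_pos=int(row["genomic_pos"]),
                ref_allele=row["ref"],
                alt_allele=row["alt"],
                mrna_offset=off,
                net_shift_d=d,
                mrna_ref=mrna_ref,
                mrna_alt=mrna_alt,
            )
        )
    logger.info(
        "load_variants: kept %d; dropped %d in-frame, %d outside CDS, "
        "%d not exonic, %d unknown transcript",
        len(variants), n_inframe, n_outside_cds, n_not_exonic, n_unknown,
    )
    return Cohort(patients=patients, variants=variants)


def write_variants(cohort: Cohort, path) -> None:
    """Serialize a cohort back to the variant TSV dialect (round-trip safe)."""
    rows = [
        (v.patient_id, v.entity, v.gene_symbol, v.transcript_id,
         v.genomic_pos, v.ref_allele or "-", v.alt_allele or "-")
        for v in cohort.variants
    ]
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "entity", "gene_symbol", "transcript_id",
                 "genomic_pos", "ref", "alt"],
    )
    df.to_csv(path, sep="\t", index=False)


def load_expression(tsv_path) -> ExpressionTable:
    """Read the gene/entity/mean_log2 expression TSV."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"gene": str, "entity": str})
    for i, raw in enumerate(df["mean_log2"]):
        try:
            float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"row {i + 2}: non-numeric expression value {raw!r}")
    dup = df.duplicated(subset=["gene", "entity"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(f"duplicate expression row for ({first['gene']}, {first['entity']})")
    values = {
        (row["gene"], row["entity"]): float(row["mean_log2"]) for _, row in df.iterrows()
    }
    return ExpressionTable(values)
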