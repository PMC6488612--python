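"""Read-level verification that a frameshift is present in expressed mRNA.

Nonsense-mediated decay could in principle remove frameshifted transcripts;
the check here is the simple RNA-seq statistic: at each frameshift site,
the fraction of overlapping reads whose alignment contains an indel at (or
within a configurable distance of) the site, gated on a minimum read depth
of 10 — below that the fraction is undefined rather than zero.

Counts can come from a precomputed ``site/total/indel`` table or directly
from a SAM/BAM alignment (via pysam, walking CIGAR strings).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "IndelSupport",
    "indel_support_fraction",
    "count_indel_support",
    "support_table",
]


@dataclass(frozen=True)
class IndelSupport:
    """Indel read support at one site."""

    site: str
    total_reads: int
    indel_reads: int
    min_reads: int = 10

    def __post_init__(self):
        if self.total_reads < 0 or self.indel_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.indel_reads > self.total_reads:
            raise ValueError("indel_reads exceeds total_reads")

    @property
    def fraction(self) -> Optional[float]:
        return indel_support_fraction(self.total_reads, self.indel_reads, self.min_reads)

    @property
    def defined(self) -> bool:
        return self.total_reads >= self.min_reads


def indel_support_fraction(
    total_reads: int, indel_reads: int, min_reads: int = 10
) -> Optional[float]:
    """Indel read fraction, or None below the minimum-depth gate."""
    if total_reads < 0 or indel_reads < 0:
        raise ValueError("read counts must be non-negative")
    if indel_reads > total_reads:
        raise ValueError("indel_reads exceeds total_reads")
    if total_reads < min_reads:
        return None
    return indel_reads / total_reads


def count_indel_support(
    alignment_path,
    contig: str,
    pos: int,
    tolerance: int = 0,
    mode: Optional[str] = None,
) -> tuple[int, int]:
    """Count (total, indel-containing) reads at a 1-based genomic position.

    A read counts toward the total when its aligned reference span covers
    ``pos``; it counts as indel support when its CIGAR places an insertion
    anchor or a deleted base within ``tolerance`` bases of ``pos``.
    SAM and BAM are both accepted (pysam; no index required).
    """
    import pysam

    pos0 = pos - 1
    total = indel = 0
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(alignment_path), mode) as af:
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.reference_name != contig:
                    continue
                if not (read.reference_start <= pos0 < (read.reference_end or 0)):
                    continue
                total += 1
                if _has_indel_near(read, pos0, tolerance):
                    indel += 1
    finally:
        pysam.set_verbosity(save)
    return total, indel


def _has_indel_near(read, pos0: int, tolerance: int) -> bool:
    ref = read.reference_start
    for op, length in read.cigartuples or ():
        if op == 1:  # insertion: anchored after reference base ref-1
            if abs((ref - 1) - pos0) <= tolerance:
                return True
        elif op == 2 or op == 3:  # deletion / skip consume reference
            if op == 2 and (ref - tolerance) <= pos0 <= (ref + length - 1 + tolerance):
                return True
            ref += length
        elif op in (0, 7, 8):  # M/=/X
            ref += length
    return False


def support_table(
    counts: pd.DataFrame, min_reads: int = 10
) -> pd.DataFrame:
    """Add ``fraction`` and ``defined`` columns to a site/total/indel table."""
    out = counts.copy()
    fracs, defined = [], []
    for _, row in out.iterrows():
        f = indel_support_fraction(int(row["total"]), int(row["indel"]), min_reads)
        defined.append(f is not None)
        fracs.append(f if f is not None else float("nan"))
    out["fraction"] = fracs
    out["defined"] = defined
    return out
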