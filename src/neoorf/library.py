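"""Recurrent-peptide library selection by greedy new-patient coverage.

NOP peptides are cut into overlapping 10-mers and pooled across the cohort;
candidates seen in at least ``min_patient_count`` patients are scanned in
descending patient count (ties broken lexicographically, so libraries are
byte-reproducible) and a peptide is accepted only if it covers at least one
patient not yet covered. This is the classic greedy maximum-coverage
heuristic restricted to new-patient gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .translate import NopRecord

logger = logging.getLogger(__name__)

__all__ = [
    "KmerRecord",
    "LibraryEntry",
    "PeptideLibrary",
    "pool_kmers",
    "build_library",
    "coverage_curve",
    "cocktail_stats",
    "write_library_tsv",
    "write_library_fasta",
]


@dataclass
class KmerRecord:
    """One pooled peptide k-mer with the patients/genes/entities carrying it."""

    peptide: str
    patients: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    entities: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class LibraryEntry:
    peptide: str
    n_patients_total: int
    newly_added_patients: frozenset[str]
    cumulative_covered: int
    genes: frozenset[str]


@dataclass
class PeptideLibrary:
    """Ordered greedy selection with incremental patient coverage."""

    entries: list[LibraryEntry]
    k: int
    min_patient_count: int

    @property
    def covered_patients(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            out |= e.newly_added_patients
        return out

    def __len__(self):
        return len(self.entries)


def pool_kmers(nops: Iterable[NopRecord], k: int = 10) -> list[KmerRecord]:
    """Cut every NOP of length >= k into its k-mers and pool by peptide.

    A patient contributing the same k-mer through several variants counts
    once; records carry the union of source genes and entities. The result
    is sorted by peptide for deterministic downstream behaviour.
    """
    pool: dict[str, KmerRecord] = {}
    for n in nops:
        pep = n.peptide
        if len(pep) < k:
            continue
        v = n.variant
        for i in range(len(pep) - k + 1):
            window = pep[i : i + k]
            rec = pool.get(window)
            if rec is None:
                rec = pool[window] = KmerRecord(window)
            rec.patients.add(v.patient_id)
            rec.genes.add(v.gene_symbol)
            rec.entities.add(v.entity)
    return [pool[p] for p in sorted(pool)]


def build_library(
    records: Iterable[KmerRecord],
    min_patient_count: int = 2,
    max_size: Optional[int] = None,
    k: int = 10,
) -> PeptideLibrary:
    """Greedy new-patient-only selection over pooled k-mer records.

    Candidates below ``min_patient_count`` patients are discarded up front;
    the rest are processed in descending patient count with lexicographic
    tie-break, accepting a peptide iff it adds at least one uncovered
    patient, stopping at ``max_size`` entries if given.
    """
    candidates = [r for r in records if len(r.patients) >= min_patient_count]
    candidates.sort(key=lambda r: (-len(r.patients), r.peptide))
    covered: set[str] = set()
    entries: list[LibraryEntry] = []
    for rec in candidates:
        if max_size is not None and len(entries) >= max_size:
            break
        new = rec.patients - covered
        if not new:
            continue
        covered |= new
        entries.append(
            LibraryEntry(
                peptide=rec.peptide,
                n_patients_total=len(rec.patients),
                newly_added_patients=frozenset(new),
                cumulative_covered=len(covered),
                genes=frozenset(rec.genes),
            )
        )
    logger.info(
        "build_library: %d entries covering %d patients (from %d candidates)",
        len(entries), len(covered), len(candidates),
    )
    return PeptideLibrary(entries=entries, k=k, min_patient_count=min_patient_count)


def coverage_curve(lib: PeptideLibrary, cohort_size: int) -> list[tuple[int, float]]:
    """Cumulative covered fraction after each accepted peptide."""
    if lib.entries and cohort_size < lib.entries[-1].cumulative_covered:
        raise ValueError("cohort_size smaller than covered patient count")
    return [
        (i + 1, e.cumulative_covered / cohort_size) for i, e in enumerate(lib.entries)
    ]


def cocktail_stats(
    lib: PeptideLibrary, records: Iterable[KmerRecord]
) -> Optional[float]:
    """Fraction of covered patients carrying two or more library peptides.

    A patient's peptide count uses full k-mer membership (every library
    peptide whose patient set contains them), not the greedy attribution.
    Returns None for an empty library (the statistic is undefined).
    """
    if not lib.entries:
        return None
    by_peptide = {r.peptide: r for r in records}
    counts: dict[str, int] = {}
    for e in lib.entries:
        for pid in by_peptide[e.peptide].patients:
            counts[pid] = counts.get(pid, 0) + 1
    covered = lib.covered_patients
    multi = sum(1 for pid in covered if counts.get(pid, 0) >= 2)
    return multi / len(covered)


def write_library_tsv(lib: PeptideLibrary, path) -> None:
    rows = [
        (rank + 1, e.peptide, e.n_patients_total, len(e.newly_added_patients),
         e.cumulative_covered, ",".join(sorted(e.genes)))
        for rank, e in enumerate(lib.entries)
    ]
    pd.DataFrame(
        rows,
        columns=["rank", "peptide", "n_patients_total", "n_new_patients",
                 "cumulative_covered", "genes"],
    ).to_csv(path, sep="\t", index=False)


def write_library_fasta(lib: PeptideLibrary, path) -> None:
    with open(path, "w") as fh:
        for rank, e in enumerate(lib.entries, start=1):
            fh.write(f">lib{rank:05d}|{e.n_patients_total}\n{e.peptide}\n")
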