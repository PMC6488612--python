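"""Cohort exclusion rules: low expression, hyper-recurrence, ORFeome overlap.

Three independent filters, each returning a new object and logging removal
counts; optional TSV audit trails record what was removed and why.

* Expression: a frameshift in a gene whose mean expression in the patient's
  tumor entity is below 2 log2 units (RNASeq-v2-style normalized counts) is
  unlikely to yield a presented peptide and is removed. Genes absent from
  the table are treated as not expressed (removed, logged separately).
* Recurrence: one identical indel seen in more than 10 distinct patients is
  suspected to be a sequencing artefact (e.g. homopolymer slippage) and the
  whole group is removed.
* ORFeome overlap: candidate peptide k-mers that also occur in the normal
  reference proteome (isoforms, chance matches) are removed.
"""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

from .models import Cohort, ExpressionTable
from .orfeome import OrfeomeIndex

logger = logging.getLogger(__name__)

__all__ = ["filter_expression", "filter_recurrence", "filter_orfeome_overlap"]


def filter_expression(
    cohort: Cohort,
    expression: ExpressionTable,
    cutoff: float = 2.0,
    audit_path=None,
) -> Cohort:
    """Drop variants whose (gene, entity) mean expression is below ``cutoff``.

    The boundary is inclusive-keep: a mean of exactly ``cutoff`` is retained.
    Absent (gene, entity) pairs are removed as not-expressed.
    """
    kept, removed = [], []
    n_absent = 0
    for v in cohort.variants:
        mean = expression.lookup(v.gene_symbol, v.entity)
        if mean is None:
            n_absent += 1
            removed.append((v, "absent"))
        elif mean < cutoff:
            removed.append((v, f"mean={mean:g}"))
        else:
            kept.append(v)
    logger.info(
        "filter_expression: removed %d of %d variants (%d with no expression entry)",
        len(removed), len(cohort.variants), n_absent,
    )
    _write_audit(audit_path, removed)
    return Cohort(patients=set(cohort.patients), variants=kept)


def filter_recurrence(cohort: Cohort, max_patients: int = 10, audit_path=None) -> Cohort:
    """Drop identical indels recurring in more than ``max_patients`` patients.

    Identity is the (transcript, mRNA offset, ref, alt) site key; recurrence
    counts distinct patients, not variant rows. Exactly ``max_patients``
    patients is kept.
    """
    patients_by_site: dict[tuple, set[str]] = {}
    for v in cohort.variants:
        patients_by_site.setdefault(v.site_key, set()).add(v.patient_id)
    hot = {k for k, pats in patients_by_site.items() if len(pats) > max_patients}
    kept = [v for v in cohort.variants if v.site_key not in hot]
    removed = [(v, f"site in {len(patients_by_site[v.site_key])} patients")
               for v in cohort.variants if v.site_key in hot]
    logger.info(
        "filter_recurrence: removed %d variants at %d hyper-recurrent sites",
        len(removed), len(hot),
    )
    _write_audit(audit_path, removed)
    return Cohort(patients=set(cohort.patients), variants=kept)


def filter_orfeome_overlap(kmers: set[str], index: OrfeomeIndex) -> set[str]:
    """Remove candidate k-mers that occur in the reference ORFeome."""
    for kmer in kmers:
        if len(kmer) != index.k:
            raise ValueError(f"k-mer {kmer!r} length {len(kmer)} != index k {index.k}")
    kept = {kmer for kmer in kmers if kmer not in index}
    logger.info(
        "filter_orfeome_overlap: removed %d of %d k-mers", len(kmers) - len(kept), len(kmers)
    )
    return kept


def _write_audit(path, removed) -> None:
    if path is None:
        return
    rows = [
        (v.patient_id, v.entity, v.gene_symbol, v.transcript_id, v.mrna_offset,
         v.mrna_ref or "-", v.mrna_alt or "-", reason)
        for v, reason in removed
    ]
    pd.DataFrame(
        rows,
        columns=["patient_id", "entity", "gene", "transcript", "mrna_offset",
                 "ref", "alt", "reason"],
    ).to_csv(path, sep="\t", index=False)
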