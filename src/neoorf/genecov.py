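"""Per-entity gene saturation coverage.

For one tumor entity, genes are ranked by the size of the largest patient
group sharing any single peptide k-mer of that gene; then, gene by gene,
peptides are added in descending patient count (lexicographic tie-break)
whenever they cover a new patient, until the gene is exhausted, before
moving to the next gene. The report gives cumulative covered fractions
after 1, 2, ... genes and after all genes — the saturation profile of a
vaccine library restricted to few genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .library import KmerRecord
from .models import Cohort

__all__ = ["GeneCoverageReport", "gene_saturation_coverage", "write_gene_coverage_tsv"]


@dataclass
class GeneCoverageReport:
    entity: str
    cohort_size: int
    genes: list[str]                 # in selection order
    peptides_per_gene: list[int]     # accepted peptides per gene
    fractions: list[float]           # cumulative fraction after each gene

    def fraction_after(self, n_genes: int) -> float:
        """Cumulative covered fraction after the first ``n_genes`` genes."""
        if n_genes <= 0 or not self.fractions:
            return 0.0
        return self.fractions[min(n_genes, len(self.fractions)) - 1]

    @property
    def fraction_all(self) -> float:
        return self.fractions[-1] if self.fractions else 0.0


def gene_saturation_coverage(
    records: Iterable[KmerRecord], cohort: Cohort, entity: str
) -> GeneCoverageReport:
    """Run the per-gene exhaustive greedy procedure for one entity.

    ``entity="ALL"`` pools the whole cohort. Ties between genes and between
    peptides are broken lexicographically. Raises for an entity with no
    patients.
    """
    entity_patients = cohort.patients_of_entity(entity)
    if not entity_patients:
        raise ValueError(f"empty entity: {entity!r}")

    # gene -> [(peptide, entity-restricted patient set)]
    per_gene: dict[str, list[tuple[str, frozenset[str]]]] = {}
    for r in records:
        pats = frozenset(r.patients & entity_patients)
        if not pats:
            continue
        for gene in r.genes:
            per_gene.setdefault(gene, []).append((r.peptide, pats))

    ranked = sorted(
        per_gene,
        key=lambda g: (-max(len(p) for _, p in per_gene[g]), g),
    )

    covered: set[str] = set()
    genes_used: list[str] = []
    peptides_per_gene: list[int] = []
    fractions: list[float] = []
    n = len(entity_patients)
    for gene in ranked:
        candidates = sorted(per_gene[gene], key=lambda it: (-len(it[1]), it[0]))
        used = 0
        for peptide, pats in candidates:
            if pats - covered:
                covered |= pats
                used += 1
        genes_used.append(gene)
        peptides_per_gene.append(used)
        fractions.append(len(covered) / n)
    return GeneCoverageReport(
        entity=entity,
        cohort_size=n,
        genes=genes_used,
        peptides_per_gene=peptides_per_gene,
        fractions=fractions,
    )


def write_gene_coverage_tsv(report: GeneCoverageReport, path) -> None:
    rows = [
        (i + 1, g, report.peptides_per_gene[i], f"{report.fractions[i]:.6f}")
        for i, g in enumerate(report.genes)
    ]
    df = pd.DataFrame(
        rows, columns=["gene_rank", "gene", "n_peptides", "cumulative_fraction"]
    )
    df.to_csv(path, sep="\t", index=False)
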