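"""End-to-end analysis: load inputs, filter, translate, select the library.

The stage order mirrors the cohort workflow: expression filter and
hyper-recurrence filter on variants, NOP translation, k-mer pooling,
reference-ORFeome exclusion, greedy library selection, coverage curves,
cocktail statistic and per-entity gene saturation. ``run_pipeline`` reads
the four input files, writes every report deterministically (byte-identical
for identical inputs) and returns the summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .filters import filter_expression, filter_orfeome_overlap, filter_recurrence
from .genecov import GeneCoverageReport, gene_saturation_coverage, write_gene_coverage_tsv
from .library import (KmerRecord, PeptideLibrary, build_library, cocktail_stats,
                      coverage_curve, pool_kmers, write_library_fasta,
                      write_library_tsv)
from .models import (Cohort, ExpressionTable, TranscriptModel, load_expression,
                     load_transcripts, load_variants)
from .orfeome import (build_orfeome_index, enumerate_pnops, map_nop_to_pnop,
                      neo_orfeome_size, write_pnop_fasta)
from .translate import NopRecord, translate_cohort, write_nop_fasta, write_nop_table

__all__ = ["PipelineParams", "AnalysisResult", "analyse", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    k: int = 10
    min_len: int = 10               # pNOP / NOP length threshold (aa)
    min_patient_count: int = 2
    expression_cutoff: float = 2.0  # log2 units
    max_recurrent_patients: int = 10
    max_library_size: Optional[int] = None


@dataclass
class AnalysisResult:
    transcripts: list[TranscriptModel]
    cohort: Cohort                   # as loaded
    filtered_cohort: Cohort          # after expression + recurrence filters
    nops: list[NopRecord]
    pnops: list
    records: list[KmerRecord]        # after ORFeome exclusion
    library: PeptideLibrary
    curve: list[tuple[int, float]]
    cocktail: Optional[float]
    gene_reports: dict[str, GeneCoverageReport]
    summary: dict = field(default_factory=dict)


def analyse(
    transcripts: list[TranscriptModel],
    cohort: Cohort,
    expression: ExpressionTable,
    params: PipelineParams = PipelineParams(),
) -> AnalysisResult:
    """Run the full in-memory analysis on loaded inputs."""
    c_expr = filter_expression(cohort, expression, params.expression_cutoff)
    c_rec = filter_recurrence(c_expr, params.max_recurrent_patients)
    nops = translate_cohort(transcripts, c_rec.variants)

    pnops = []
    for t in transcripts:
        pnops.extend(enumerate_pnops(t, min_len=params.min_len))
    total_aa, total_nt = neo_orfeome_size(pnops)

    index = build_orfeome_index(transcripts, k=params.k)
    pooled = pool_kmers(nops, k=params.k)
    kept_kmers = filter_orfeome_overlap({r.peptide for r in pooled}, index)
    records = [r for r in pooled if r.peptide in kept_kmers]

    library = build_library(records, params.min_patient_count,
                            params.max_library_size, k=params.k)
    curve = coverage_curve(library, cohort.n_patients)
    cocktail = cocktail_stats(library, records)

    gene_reports = {"ALL": gene_saturation_coverage(records, cohort, "ALL")}
    for entity in sorted(cohort.entities):
        gene_reports[entity] = gene_saturation_coverage(records, cohort, entity)

    unique_nops = {n.peptide for n in nops if len(n.peptide) >= params.min_len}
    summary = {
        "n_patients": cohort.n_patients,
        "n_variants_loaded": len(cohort.variants),
        "n_removed_expression": len(cohort.variants) - len(c_expr.variants),
        "n_removed_recurrence": len(c_expr.variants) - len(c_rec.variants),
        "n_variants_analysed": len(c_rec.variants),
        "n_unique_nop_peptides_min_len": len(unique_nops),
        "n_pnops": len(pnops),
        "neo_orfeome_aa": total_aa,
        "neo_orfeome_nt": total_nt,
        "n_kmers_pooled": len(pooled),
        "n_kmers_removed_orfeome": len(pooled) - len(records),
        "library_size": len(library),
        "covered_patients": len(library.covered_patients),
        "covered_fraction": round(len(library.covered_patients) / cohort.n_patients, 6),
        "first_coverage_fraction": round(curve[0][1], 6) if curve else 0.0,
        "cocktail_fraction": None if cocktail is None else round(cocktail, 6),
    }
    return AnalysisResult(
        transcripts=transcripts, cohort=cohort, filtered_cohort=c_rec,
        nops=nops, pnops=pnops, records=records, library=library,
        curve=curve, cocktail=cocktail, gene_reports=gene_reports,
        summary=summary,
    )


def convergence_report(result: AnalysisResult) -> str:
    """Text report: how distinct frameshift sites converge onto pNOPs.

    One line per pNOP that at least one NOP maps onto, listing the distinct
    protein-start positions of the converging frameshift sites.
    """
    by_tid: dict[str, list] = {}
    for p in result.pnops:
        by_tid.setdefault(p.transcript_id, []).append(p)
    hits: dict[tuple, set[int]] = {}
    for nop in result.nops:
        pnops = by_tid.get(nop.variant.transcript_id, [])
        found = map_nop_to_pnop(nop, pnops)
        if found is None:
            continue
        p, _ = found
        key = (p.transcript_id, p.frame_label, p.start_offset, len(p.peptide))
        hits.setdefault(key, set()).add(nop.protein_start)
    lines = ["# transcript\tframe\tpnop_start\tpnop_len\tn_sites\tsite_protein_starts"]
    for (tid, frame, start, ln), sites in sorted(hits.items()):
        lines.append(
            f"{tid}\t{frame}\t{start}\t{ln}\t{len(sites)}\t"
            + ",".join(str(s) for s in sorted(sites))
        )
    return "\n".join(lines) + "\n"


def run_pipeline(
    fasta_path, model_path, variants_path, expression_path, outdir,
    params: PipelineParams = PipelineParams(),
) -> AnalysisResult:
    """Load the input bundle, analyse, and write all reports to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = load_transcripts(fasta_path, model_path)
    cohort = load_variants(variants_path, transcripts)
    expression = load_expression(expression_path)
    result = analyse(transcripts, cohort, expression, params)

    write_nop_table(result.nops, outdir / "nops.tsv")
    write_nop_fasta(result.nops, outdir / "nops.fasta")
    write_pnop_fasta(result.pnops, outdir / "pnops.fasta")
    build_orfeome_index(transcripts, k=params.k).to_text(outdir / "orfeome_kmers.txt")
    write_library_tsv(result.library, outdir / "library.tsv")
    write_library_fasta(result.library, outdir / "library.fasta")
    with open(outdir / "coverage.tsv", "w") as fh:
        fh.write("n_peptides\tfraction_covered\n")
        for n, f in result.curve:
            fh.write(f"{n}\t{f:.6f}\n")
    for entity, report in sorted(result.gene_reports.items()):
        write_gene_coverage_tsv(report, outdir / f"gene_coverage_{entity}.tsv")
    with open(outdir / "convergence_report.txt", "w") as fh:
        fh.write(convergence_report(result))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
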