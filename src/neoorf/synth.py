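"""Deterministic synthetic transcriptomes, frameshift cohorts and expression.

Every stage of the pipeline is testable without external data: this module
emulates the statistical structure of a tumor-cohort input bundle with
*planted ground truth* recorded in a manifest —

* a transcriptome of random-codon CDSs (ATG ... stop + 3'UTR) on both
  strands, split into exons and placed on synthetic contigs;
* a patient cohort with a planted recurrent frameshift shared by a fixed
  fraction of patients, a second overlapping recurrent event (so some
  patients carry a peptide cocktail), a planted convergent pair (two
  same-gene, same-frame events at different positions whose neo-peptides
  share a suffix), a hyper-recurrent artefact site (> 10 patients), events
  in silent genes, and uniform private background frameshifts in the
  remaining patients;
* an expression table where planted silent genes fall below the 2-log2
  cutoff in every entity and all other genes sit above it;
* a decoy transcript whose in-frame protein contains one k-mer of the
  planted neo-peptide, so the reference-ORFeome filter has a planted hit.

All randomness flows through one ``numpy`` generator seeded from
``SynthSpec.seed``; the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from ._codon import CODON_TO_AA, STOP_CODONS
from .models import Cohort, ExpressionTable, FrameshiftVariant, TranscriptModel
from .translate import NopRecord, translate_nop

__all__ = [
    "SynthSpec",
    "make_transcriptome",
    "write_transcriptome",
    "plant_cohort",
    "make_variant",
    "make_expression_table",
    "generate_bundle",
]

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
_ALL_CODONS = sorted(CODON_TO_AA)
# first codon (alphabetically) per amino acid, for reverse translation
_AA_TO_CODON: dict[str, str] = {}
for _codon in _ALL_CODONS:
    _AA_TO_CODON.setdefault(CODON_TO_AA[_codon], _codon)


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic cohort.

    Defaults are the conditions every test and the acceptance script run
    under: 200 patients in three entities, one recurrent frameshift planted
    in 30% of patients, a second recurrent event overlapping it (cocktail
    patients), a convergent same-gene pair, a > 10-patient artefact site,
    two silent genes, one reference-ORFeome collision, and one private
    background frameshift for every remaining patient.
    """

    seed: int = 0
    n_transcripts: int = 30
    cds_codons: tuple[int, int] = (120, 300)
    utr5_nt: tuple[int, int] = (0, 30)
    utr3_nt: tuple[int, int] = (60, 180)
    n_patients: int = 200
    entities: tuple[tuple[str, float], ...] = (
        ("COAD", 0.5), ("UCEC", 0.3), ("LUSC", 0.2),
    )
    recurrent_fraction: float = 0.30
    recurrent2_fraction: float = 0.10
    recurrent2_overlap: float = 0.50   # of event-2 patients also in event 1
    convergent_pair_patients: int = 4  # per member of the planted pair
    artefact_patients: int = 12
    n_silent_genes: int = 2
    silent_gene_patients: int = 3
    plant_orfeome_collision: bool = True
    background_fs_per_patient: int = 1
    allow_internal_stops: bool = False
    kmer_len: int = 10

    def __post_init__(self):
        for _, f in self.entities:
            if not 0 <= f <= 1:
                raise ValueError("entity proportions must lie in [0, 1]")
        for f in (self.recurrent_fraction, self.recurrent2_fraction,
                  self.recurrent2_overlap):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.cds_codons[0] < 20 or self.cds_codons[0] > self.cds_codons[1]:
            raise ValueError("impossible CDS length range")


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_transcriptome(spec: SynthSpec) -> list[TranscriptModel]:
    """Generate ``n_transcripts`` exon-split transcript models.

    Each CDS begins with ATG and ends with a stop codon; interior codons are
    uniform over the 61 sense codons (or all 64 when
    ``allow_internal_stops``). Strands alternate so both are always
    represented.
    """
    rng = np.random.default_rng(spec.seed)
    interior_pool = _ALL_CODONS if spec.allow_internal_stops else _NONSTOP_CODONS
    models: list[TranscriptModel] = []
    for i in range(spec.n_transcripts):
        n_codons = int(rng.integers(spec.cds_codons[0], spec.cds_codons[1] + 1))
        utr5 = _random_seq(rng, int(rng.integers(spec.utr5_nt[0], spec.utr5_nt[1] + 1)))
        utr3 = _random_seq(rng, int(rng.integers(spec.utr3_nt[0], spec.utr3_nt[1] + 1)))
        interior = "".join(
            interior_pool[j] for j in rng.integers(0, len(interior_pool), size=n_codons - 2)
        )
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        mrna = utr5 + "ATG" + interior + stop + utr3
        strand = "+" if i % 2 == 0 else "-"
        models.append(
            _place_on_genome(
                rng, mrna, strand,
                transcript_id=f"TX{i:04d}", gene_symbol=f"G{i:04d}",
                contig=f"chr{1 + i % 5}", genomic_anchor=10_000 + i * 1_000_000,
                cds_start=len(utr5), cds_end=len(utr5) + 3 * n_codons,
            )
        )
    return models


def _place_on_genome(rng, mrna, strand, transcript_id, gene_symbol, contig,
                     genomic_anchor, cds_start, cds_end) -> TranscriptModel:
    """Split the transcript into 1-3 exons and assign genomic intervals."""
    length = len(mrna)
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else []
    bounds = [0, *map(int, cuts), length]
    exon_lens = [bounds[j + 1] - bounds[j] for j in range(n_exons)]
    exons_fwd: list[tuple[int, int]] = []
    g = genomic_anchor
    for ln in exon_lens:
        exons_fwd.append((g, g + ln - 1))
        g += ln + int(rng.integers(50, 500))
    exons = tuple(exons_fwd if strand == "+" else exons_fwd[::-1])
    return TranscriptModel(
        transcript_id=transcript_id, gene_symbol=gene_symbol, contig=contig,
        strand=strand, mrna_sequence=mrna, cds_start=cds_start, cds_end=cds_end,
        exons=exons,
    )


def write_transcriptome(models: list[TranscriptModel], fasta_path, model_path) -> None:
    """Write the FASTA (forward genomic strand) + model TSV pair."""
    with open(fasta_path, "w") as fh:
        for t in models:
            seq = t.mrna_sequence
            if t.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            fh.write(f">{t.transcript_id}\n{seq}\n")
    with open(model_path, "w") as fh:
        fh.write("transcript_id\tgene_symbol\tcontig\tstrand\texon_starts\t"
                 "exon_ends\tcds_start\tcds_end\n")
        for t in models:
            asc = sorted(t.exons)
            fh.write(
                f"{t.transcript_id}\t{t.gene_symbol}\t{t.contig}\t{t.strand}\t"
                f"{','.join(str(s) for s, _ in asc)}\t"
                f"{','.join(str(e) for _, e in asc)}\t{t.cds_start}\t{t.cds_end}\n"
            )


# ---------------------------------------------------------------------------
# cohort planting
# ---------------------------------------------------------------------------


def _genomic_alleles(t: TranscriptModel, x: int, mrna_ref: str, mrna_alt: str):
    """mRNA-space edit -> (genomic_pos, ref, alt) in the file dialect."""
    rc = lambda s: str(Seq(s).reverse_complement())
    if mrna_ref:
        if t.strand == "+":
            return t.map_mrna_to_genomic(x), mrna_ref, (mrna_alt or "-")
        gpos = t.map_mrna_to_genomic(x + len(mrna_ref) - 1)
        return gpos, rc(mrna_ref), (rc(mrna_alt) if mrna_alt else "-")
    if t.strand == "+":
        return t.map_mrna_to_genomic(x - 1), "-", mrna_alt
    return t.map_mrna_to_genomic(x), "-", rc(mrna_alt)


def make_variant(t: TranscriptModel, x: int, mrna_ref: str, mrna_alt: str,
                  patient_id: str, entity: str) -> FrameshiftVariant:
    gpos, ref, alt = _genomic_alleles(t, x, mrna_ref, mrna_alt)
    return FrameshiftVariant(
        patient_id=patient_id, entity=entity, gene_symbol=t.gene_symbol,
        transcript_id=t.transcript_id, genomic_pos=gpos,
        ref_allele=ref, alt_allele=alt, mrna_offset=x,
        net_shift_d=len(mrna_alt) - len(mrna_ref),
        mrna_ref=mrna_ref, mrna_alt=mrna_alt,
    )


def _probe_nop(t: TranscriptModel, x: int, mrna_ref: str, mrna_alt: str) -> NopRecord:
    return translate_nop(t, make_variant(t, x, mrna_ref, mrna_alt, "_probe", "_probe"))


def _probe_site(t: TranscriptModel, kind: str, codon: int, base: str = "A") -> tuple:
    """(mrna_offset, mrna_ref, mrna_alt, NopRecord) for one candidate site."""
    if kind == "del1":
        x = t.cds_start + 3 * codon
        ref, alt = t.mrna_sequence[x], ""
    elif kind == "ins1":
        x = t.cds_start + 3 * codon + 1
        ref, alt = "", base
    else:
        raise ValueError(f"unknown site kind {kind!r}")
    return x, ref, alt, _probe_nop(t, x, ref, alt)


def _find_cluster(t: TranscriptModel, kind: str, codon_offsets: list[int],
                  min_tail: int, max_len: int, base: str = "A"):
    """Find converging sites at the given relative codon spacings.

    Distinct frameshifts upstream of the same shifted-frame stop converge on
    a shared peptide suffix; this scans for a start codon where every site
    in the cluster yields a terminated NOP with the regular nesting pattern
    (each NOP one residue shorter per codon moved 3'), the shortest NOP is
    at least ``min_tail`` residues, and the longest at most ``max_len``.
    Returns ``(sites, shared_suffix)`` where each site is
    ``(mrna_offset, mrna_ref, mrna_alt, NopRecord)``.
    """
    n_codons = (t.cds_end - t.cds_start) // 3
    span = max(codon_offsets)
    for c0 in range(5, n_codons - span - 3):
        sites = [_probe_site(t, kind, c0 + off, base) for off in codon_offsets]
        nops = [s[3] for s in sites]
        if not all(n.terminated for n in nops):
            continue
        len0 = len(nops[0].peptide)
        if not (min_tail + span - codon_offsets[0] <= len0 <= max_len):
            continue
        if all(len(n.peptide) == len0 - (off - codon_offsets[0])
               for n, off in zip(nops, codon_offsets)):
            shared = _common_suffix([n.peptide for n in nops])
            if len(shared) >= min_tail:
                return sites, shared
    raise ValueError(f"no suitable {kind} cluster on {t.transcript_id}")


def _common_suffix(strings: list[str]) -> str:
    rev = [s[::-1] for s in strings]
    out = []
    for chars in zip(*rev):
        if len(set(chars)) != 1:
            break
        out.append(chars[0])
    return "".join(out)[::-1]


def _entity_blocks(spec: SynthSpec) -> list[tuple[str, str]]:
    """Deterministic (patient_id, entity) assignment by largest remainder."""
    n = spec.n_patients
    raw = [(name, f * n) for name, f in spec.entities]
    counts = {name: int(np.floor(q)) for name, q in raw}
    short = n - sum(counts.values())
    for name, _ in sorted(raw, key=lambda it: (-(it[1] - np.floor(it[1])), it[0]))[:short]:
        counts[name] += 1
    out: list[tuple[str, str]] = []
    i = 0
    for name, _ in spec.entities:
        for _ in range(counts[name]):
            out.append((f"P{i:04d}", name))
            i += 1
    return out


def plant_cohort(
    spec: SynthSpec, transcripts: list[TranscriptModel]
) -> tuple[Cohort, dict, list[TranscriptModel]]:
    """Plant the cohort onto an existing transcriptome.

    Returns ``(cohort, manifest, extra_transcripts)`` where
    ``extra_transcripts`` holds the ORFeome-collision decoy (to be appended
    to the transcriptome before building the reference index). Host
    transcripts for planted events are the first six models; background
    private frameshifts are confined to the remaining transcripts so that
    planted patient counts, coverage fractions and filter removal counts in
    the manifest are exact by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    k = spec.kmer_len
    if len(transcripts) < 7:
        raise ValueError("need at least 7 transcripts to plant the default events")
    host_rec1, host_conv, host_artefact, host_sil1, host_sil2, host_rec2 = transcripts[:6]
    background_hosts = transcripts[6:]
    silent_genes = [host_sil1.gene_symbol, host_sil2.gene_symbol][: spec.n_silent_genes]

    patients = _entity_blocks(spec)
    entity_of = dict(patients)
    order = [patients[i][0] for i in rng.permutation(len(patients))]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        if cursor + n > len(order):
            raise ValueError("not enough patients for the planted events")
        chunk = order[cursor : cursor + n]
        cursor += n
        return chunk

    variants: list[FrameshiftVariant] = []
    events: list[dict] = []

    def plant(name, t, x, mrna_ref, mrna_alt, pids):
        nop = _probe_nop(t, x, mrna_ref, mrna_alt)
        for pid in pids:
            variants.append(make_variant(t, x, mrna_ref, mrna_alt, pid, entity_of[pid]))
        events.append({
            "name": name, "transcript_id": t.transcript_id,
            "gene_symbol": t.gene_symbol, "mrna_offset": x,
            "mrna_ref": mrna_ref, "mrna_alt": mrna_alt,
            "frame_label": nop.frame_label, "protein_start": nop.protein_start,
            "nop_peptide": nop.peptide, "terminated": nop.terminated,
            "patients": sorted(pids),
        })
        return nop

    # 1) main recurrent peptide: distinct 1-bp deletions at consecutive
    #    codons converging on a shared suffix, carried by recurrent_fraction
    #    of patients (each individual site stays at <= 10 patients, so the
    #    artefact rule does not fire — recurrence of the *peptide* arises
    #    from convergence, not from one identical indel)
    n_rec1 = round(spec.recurrent_fraction * spec.n_patients)
    per_site = 10
    n_sites1 = -(-n_rec1 // per_site)
    rec1_sites, rec1_shared = _find_cluster(
        host_rec1, "del1", list(range(n_sites1)), min_tail=k + 3, max_len=90)
    rec1_pids = take(n_rec1)
    for i, (x, ref, alt, _) in enumerate(rec1_sites):
        pids = rec1_pids[i * per_site : (i + 1) * per_site]
        if pids:
            plant(f"recurrent_main_site{i}", host_rec1, x, ref, alt, pids)

    # 2) second recurrent peptide (1-bp insertions), patient set overlapping
    #    event 1 so some patients carry a two-peptide cocktail
    n_rec2 = round(spec.recurrent2_fraction * spec.n_patients)
    n_shared = round(spec.recurrent2_overlap * n_rec2)
    rec2_pids = rec1_pids[:n_shared] + take(n_rec2 - n_shared)
    n_sites2 = -(-n_rec2 // per_site)
    ins_base = "ACGT"[int(rng.integers(0, 4))]
    rec2_sites, rec2_shared = _find_cluster(
        host_rec2, "ins1", list(range(n_sites2)), min_tail=k + 3, max_len=90,
        base=ins_base)
    for i, (x, ref, alt, _) in enumerate(rec2_sites):
        pids = rec2_pids[i * per_site : (i + 1) * per_site]
        if pids:
            plant(f"recurrent_overlap_site{i}", host_rec2, x, ref, alt, pids)

    # 3) convergent pair: two del1 events, same gene, same frame class,
    #    ten codons apart, second junction inside the first NOP's run
    conv_sites, conv_shared = _find_cluster(
        host_conv, "del1", [0, 10], min_tail=k + 2, max_len=140)
    (xa, ref_a, alt_a, conv_a) = conv_sites[0]
    (xb, ref_b, alt_b, conv_b) = conv_sites[1]
    plant("convergent_a", host_conv, xa, ref_a, alt_a,
          take(spec.convergent_pair_patients))
    plant("convergent_b", host_conv, xb, ref_b, alt_b,
          take(spec.convergent_pair_patients))

    # 4) hyper-recurrent artefact site (removed by the >10-patient rule)
    xart = host_artefact.cds_start + 30
    plant("artefact", host_artefact, xart, host_artefact.mrna_sequence[xart], "",
          take(spec.artefact_patients))

    # 5) events in silent genes (removed by the expression filter)
    n_silent_rows = 0
    silent_hosts = list(zip(("silent_1", "silent_2"), (host_sil1, host_sil2)))
    for name, host in silent_hosts[: spec.n_silent_genes]:
        xs = host.cds_start + 30
        plant(name, host, xs, host.mrna_sequence[xs], "",
              take(spec.silent_gene_patients))
        n_silent_rows += spec.silent_gene_patients

    # 6) background: private frameshifts in every remaining patient
    background_pids = order[cursor:]
    kinds = [("del", 1), ("ins", 1), ("del", 2), ("ins", 2)]
    for pid in background_pids:
        for _ in range(spec.background_fs_per_patient):
            t = background_hosts[int(rng.integers(0, len(background_hosts)))]
            kind, ln = kinds[int(rng.integers(0, 4))]
            lo, hi = t.cds_start, t.cds_end - 3 - ln
            x = int(rng.integers(lo, hi))
            if kind == "del":
                variants.append(make_variant(
                    t, x, t.mrna_sequence[x : x + ln], "", pid, entity_of[pid]))
            else:
                ins = _random_seq(rng, ln)
                variants.append(make_variant(t, x, "", ins, pid, entity_of[pid]))

    # 7) decoy transcript carrying one shared planted k-mer in frame.
    #    Buffer residues on both sides are chosen to differ from the
    #    residues flanking the k-mer inside the planted NOPs, so the decoy
    #    contributes exactly one colliding k-mer to the reference index.
    extra: list[TranscriptModel] = []
    collision_kmer = None
    if spec.plant_orfeome_collision and len(rec1_shared) >= k + 1:
        collision_kmer = rec1_shared[:k]
        rec1_nops = [s[3] for s in rec1_sites]
        preceding = {n.peptide[-(len(rec1_shared) + 1)]
                     for n in rec1_nops if len(n.peptide) > len(rec1_shared)}
        left_aa = next(a for a in "WYFHKRDE" if a not in preceding)
        right_aa = next(a for a in "WYFHKRDE" if a != rec1_shared[k])
        pad = "".join(_NONSTOP_CODONS[j] for j in rng.integers(
            0, len(_NONSTOP_CODONS), size=12))
        cds = ("ATG" + _AA_TO_CODON[left_aa]
               + "".join(_AA_TO_CODON[a] for a in collision_kmer)
               + _AA_TO_CODON[right_aa] + pad + "TAA")
        decoy_mrna = cds + _random_seq(rng, 60)
        extra.append(_place_on_genome(
            rng, decoy_mrna, "+", transcript_id="TXDECOY", gene_symbol="GDECOY",
            contig="chr9", genomic_anchor=500_000_000,
            cds_start=0, cds_end=len(cds),
        ))

    rec1_kmers = {rec1_shared[i : i + k] for i in range(len(rec1_shared) - k + 1)}
    top_candidates = rec1_kmers - ({collision_kmer} if collision_kmer else set())
    per_entity_rec1 = {}
    for pid in rec1_pids:
        per_entity_rec1[entity_of[pid]] = per_entity_rec1.get(entity_of[pid], 0) + 1

    manifest = {
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "entity_counts": {name: sum(1 for _, e in patients if e == name)
                          for name, _ in spec.entities},
        "events": events,
        "silent_genes": silent_genes,
        "expected_expression_removed_rows": n_silent_rows,
        "expected_recurrence_removed_rows": spec.artefact_patients,
        "orfeome_collision_kmer": collision_kmer,
        "expected_orfeome_removed_kmers": 1 if collision_kmer else 0,
        "expected_top_peptide": min(top_candidates),
        "expected_top_patient_count": n_rec1,
        "expected_top_fraction": n_rec1 / spec.n_patients,
        "expected_top_gene": host_rec1.gene_symbol,
        "rec1_shared_suffix": rec1_shared,
        "rec2_shared_suffix": rec2_shared,
        "rec1_patients_per_entity": per_entity_rec1,
        "expected_shared_suffix": conv_b.peptide[1:],
        "convergent_frame": conv_a.frame_label,
        "n_background_patients": len(background_pids),
        "n_variant_rows": len(variants),
    }
    cohort = Cohort(patients=set(patients), variants=variants)
    return cohort, manifest, extra


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def make_expression_table(
    spec: SynthSpec, gene_symbols: list[str], silent_genes: list[str]
) -> ExpressionTable:
    """Full (gene x entity) grid: silent genes at 0.5, the rest >= 2 log2."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    values: dict[tuple[str, str], float] = {}
    for gene in gene_symbols:
        for entity, _ in spec.entities:
            if gene in silent_genes:
                values[(gene, entity)] = 0.5
            else:
                values[(gene, entity)] = round(2.0 + 8.0 * float(rng.random()), 3)
    return ExpressionTable(values)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


def generate_bundle(spec: SynthSpec, outdir) -> dict[str, Path]:
    """Write the full synthetic input bundle plus ``manifest.json``.

    Produces ``transcripts.fasta``, ``transcripts.tsv``, ``variants.tsv``,
    ``expression.tsv`` and ``manifest.json`` under ``outdir`` and returns
    their paths. Byte-identical for identical specs.
    """
    from .models import write_variants

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = make_transcriptome(spec)
    cohort, manifest, extra = plant_cohort(spec, models)
    all_models = models + extra
    paths = {
        "fasta": outdir / "transcripts.fasta",
        "models": outdir / "transcripts.tsv",
        "variants": outdir / "variants.tsv",
        "expression": outdir / "expression.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_transcriptome(all_models, paths["fasta"], paths["models"])
    write_variants(cohort, paths["variants"])
    expr = make_expression_table(
        spec, [t.gene_symbol for t in all_models], manifest["silent_genes"]
    )
    expr.to_tsv(paths["expression"])
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
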