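# Methods

## Model and procedure

**Coordinates.** Genomic positions are 1-based inclusive (MAF convention);
all internal mRNA/CDS offsets are 0-based half-open. A transcript model
carries the mRNA sequence (5'→3', mRNA orientation), the CDS window
`[cds_start, cds_end)` (stop codon included, length a multiple of 3), and
the ordered genomic exon intervals. Minus-strand sequences and alleles are
reverse-complemented once at load; every downstream computation is pure
mRNA-space string arithmetic. The genomic↔mRNA map is a bijection over
exonic positions and is tested exhaustively on both strands.

**Frame classes.** For a net indel length change `d` (`d mod 3 ≠ 0`),
downstream reference bases are read at offsets congruent to +1 relative to
the annotated frame when `d ≡ 2 (mod 3)` (e.g. a 1-bp deletion) — labelled
`+1` — and at −1 offsets when `d ≡ 1 (mod 3)` (e.g. a 1-bp insertion) —
labelled `-1`. The labels are a fixed convention of this package; the
literature uses −1/+1 without an operational definition, so only internal
consistency (NOP ↔ pNOP frames agree) is meaningful.

**NOP translation.** The mutant mRNA is the reference with the edit
applied at the offset of the first changed base (a reference-allele
mismatch is a hard error). Translation proceeds in the annotated frame
from `cds_start`; the NOP is the suffix from the *junction codon* — the
codon containing the first changed base — to the first stop codon at or
after it, stop excluded. Translation deliberately continues through the
annotated 3'UTR: an in-frame stop does not terminate a shifted frame, and
shifted-frame open runs frequently extend past the annotated CDS. If no
stop arrives before the transcript end the NOP is kept and flagged
unterminated. The junction codon mixes reference and edited bases; the
number of such leading residues (`junction_len`, 1 for 1-bp events, 2 when
a multi-base insertion spills into the next codon) is recorded, and only
the pure-reference suffix beyond them is used for pNOP matching. The
standard nuclear code is used; codons containing ambiguous bases translate
to `X`, and `X`-containing windows never match any k-mer query.

**pNOP enumeration.** For each frame the scan starts at the first full
codon of that frame at/after `cds_start` (`+1`: `cds_start+1`, `-1`:
`cds_start+2`) and runs to the transcript 3' end (configurable to stop at
`cds_end`), splitting at stop codons and keeping stop-free segments of at
least `min_len` residues (default 10, configurable — 8 raises coverage at
the cost of weaker epitope specificity). Segments cut by the transcript
end are kept and flagged, mirroring the NOP rule. The scan is restricted
to frames reachable by a single simple frameshift within the CDS — not a
genome-wide six-frame scan, which would count sequence no real frameshift
can reach. Because both AA and NT totals are meaningful sizes for the
Neo-ORFeome, `neo_orfeome_size` reports both.

**NOP→pNOP mapping.** A NOP's post-junction suffix is located by substring
search among same-frame pNOPs of its transcript. Short suffixes can occur
in several segments by chance; the true template is the segment whose mRNA
interval contains the point where reference sequence resumes after the
edit — unique, because same-frame segments are disjoint. Residual
ambiguity indicates a corrupt pNOP set and raises.

**Filters.** (1) Expression: variants in genes whose mean log2 expression
in the patient's entity is below 2.0 are removed; the boundary is
inclusive-keep (exactly 2.0 is retained), and genes absent from the table
are treated as not expressed (removed, logged separately) — the
conservative reading. (2) Recurrence: the *identical* event key
(transcript, mRNA offset, ref, alt) found in more than 10 *distinct
patients* is removed entirely as a suspected artefact; exactly 10 is kept.
(3) ORFeome: candidate 10-mers present among the tiled 10-mers of any
reference in-frame protein are removed (isoforms and chance matches).
Filters are order-independent on variants (tested); the pipeline applies
expression and recurrence before translation and k-mer pooling.

**Library selection.** NOPs ≥ k residues are cut into all k-mers
(k = 10); records pool distinct patients (a patient contributing a k-mer
via several variants counts once) plus gene/entity sets. Candidates with
fewer than `min_patient_count` patients (default 2) are discarded; the
rest are scanned in descending patient count with lexicographic tie-break
— ties are real and the tie-break is what makes libraries byte-
reproducible — accepting a peptide iff it adds ≥ 1 uncovered patient.
The cocktail statistic counts, among covered patients, those contained in
the patient sets of ≥ 2 *accepted* peptides (full membership, not greedy
attribution). The coverage curve divides cumulative covered patients by
the full cohort size, dropped variants included.

**Gene saturation coverage.** Per entity, genes are ranked by their
largest single-peptide patient group (not the gene-level union — the
ambiguous phrase is resolved this way and implemented in one place);
within a gene, peptides are added in descending patient count while they
add new patients, then the next gene, until exhaustion. Coverage after
"all genes" provably equals a `min_patient_count=1` greedy library's
coverage on the same records, which is asserted in tests. `entity="ALL"`
pools the cohort.

**RNA support.** The indel-support statistic is
`indel_reads / total_reads`, *undefined* (not zero) below a 10-read depth
gate. Counts come from a site/total/indel table or from SAM/BAM via pysam:
a read counts toward the total when its aligned span covers the site, and
as indel support when its CIGAR places an insertion anchor or deleted base
within `tolerance` bases of the site (default 0). Aligner-specific tags
are deliberately not used.

## Synthetic study conditions

The generator is the single source of test data; all randomness flows
through one seeded numpy generator, and identical specs give byte-identical
files. Defaults (chosen once as the study conditions):

| parameter | value | why |
|---|---|---|
| patients | 200 | large enough for stable fractions, small enough for sub-second runs |
| entities | COAD/UCEC/LUSC at 0.5/0.3/0.2 | three unequal strata |
| transcripts | 30 × 120–300 codons, alternating strands, 1–3 exons | both strands and split exons always exercised |
| recurrent peptide | 30% of patients (60), via 6 distinct 1-bp deletions at consecutive codons, 10 patients each | recurrence must arise from *convergence*: a single identical indel in 60 patients would (correctly) be removed by the artefact rule; 10 per site also pins the ≤10 boundary |
| second recurrent peptide | 10% of patients, 1-bp insertions, half its carriers shared with the first | creates true cocktail patients |
| convergent pair | 2 deletions, same gene/frame, 10 codons apart, 4 patients each | planted check that distinct sites share a pNOP suffix |
| artefact site | one identical deletion in 12 patients | exceeds the >10 rule by a margin |
| silent genes | 2 genes at 0.5 log2, 3 patients each | expression-filter ground truth |
| ORFeome collision | one shared planted 10-mer re-encoded in-frame in a decoy transcript | reference-overlap ground truth; decoy boundary residues are chosen so exactly one k-mer collides |
| background | 1 private 1–2 bp indel per remaining patient, on non-host transcripts only | keeps planted counts exact while still producing organic convergence among background patients |

The manifest records every planted event, the expected top library peptide
(the lexicographically smallest shared 10-mer surviving the ORFeome
filter), its exact prevalence (0.30), the expected filter removal counts
and the convergent pair's shared suffix. What the generator does *not*
emulate: mutational signatures, indel-length spectra, NMD, per-sample
expression, sequencing error, multi-exon-spanning deletions, or splice-site
/ double-frameshift complex events. Passing tests therefore demonstrate
algorithmic correctness under the stated model, not performance on real
cohorts, whose headline numbers depend on database versions and cohort
sizes far beyond desk scale.

## Numerical and design notes

* **Geometric length check.** On uniform random codons each shifted-frame
  codon is a stop with probability 3/64, so the codon count from the
  junction up to and including the stop is geometric with mean
  64/3 ≈ 21.33. The check uses 10,000 frameshifts on 10,000 *independent*
  transcripts (one each): variants sharing a transcript share downstream
  stop positions, which correlates waits and inflates the variance well
  past the iid standard error. Positions are drawn from the first third of
  a 300-codon CDS whose interior codons are uniform over all 64, so runs
  terminate inside uniform sequence; shifted-frame codons straddling the
  forced terminal stop codon can never themselves be stops and would
  otherwise bias waits upward. The assertion is three standard errors —
  a statistical bound, run with a fixed seed.
* **Determinism.** No iteration over unordered sets reaches any output:
  pooled k-mers are sorted, greedy ties broken lexicographically, reports
  sorted, JSON keys sorted. Two pipeline runs from one seed are
  byte-identical (tested at file level).
* **Degenerate inputs.** Empty cohorts, empty libraries (cocktail fraction
  is `None`, not 0), all-stop frames, proteins shorter than k, and empty
  NOPs (junction codon is itself a stop) are all defined cases with tests.
* **Boundary decisions.** Expression `== cutoff` keep; recurrence `== 10`
  keep; depth `== 10` defined — each stated in the docstrings and pinned
  in tests.
* **Unrepresentable edits.** The MAF insertion dialect anchors on the base
  5' of the insertion point, so an insertion before mRNA position 0 cannot
  be expressed; samplers start insertion offsets at 1.

## Limitations

Binding prediction (MHC class I) is out of scope: `OrfeomeIndex`-style
membership hooks accept externally produced binding labels, but no
predictor is bundled. Transcript models are inputs; the package does not
align mRNAs to a genome build and is build-agnostic (the caller must keep
variants and models on one build). VCF ingestion and full GTF/GFF parsing
are future work; the documented TSV dialects plus FASTA are the supported
interchange. Somatic SNVs co-occurring on the NOP haplotype,
selenocysteine readthrough, and NMD quantification are not modelled.
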