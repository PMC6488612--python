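"""Standard-nuclear-code codon helpers used by the frameshift translator.

The table is built once from Biopython's standard codon table; stop codons map
to ``*`` and any codon containing a non-ACGT base (e.g. ``N``) maps to ``X``.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]

CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)


def translate_codon(codon: str) -> str:
    """Translate one codon; ambiguous/invalid codons give ``X``."""
    return CODON_TO_AA.get(codon, "X")


def translate_until_stop(seq: str, start: int) -> tuple[str, bool]:
    """Translate ``seq`` codon-by-codon from ``start`` until a stop codon.

    Returns ``(peptide, terminated)``. The stop residue is excluded from the
    peptide; ``terminated`` is False when the sequence runs out (fewer than
    three nucleotides left) before any stop codon is seen.
    """
    out: list[str] = []
    pos = start
    n = len(seq)
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            return "".join(out), True
        out.append(CODON_TO_AA.get(codon, "X"))
        pos += 3
    return "".join(out), False
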