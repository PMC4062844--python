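"""Standard genetic-code lookups shared by the divergence and simulation modules.

Everything here is derived once, at import time, from Biopython's standard
nuclear codon table, so the classification of a substitution as synonymous or
nonsynonymous has a single source of truth across the package.
"""
from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, ``*`` for a stop codon.

    Raises KeyError for codons containing non-ACGT characters.
    """
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def _fourfold_codons() -> frozenset[str]:
    out = set()
    for codon in SENSE_CODONS:
        family = [codon[:2] + b for b in BASES]
        if all(c in CODON_TO_AA for c in family):
            aas = {CODON_TO_AA[c] for c in family}
            if len(aas) == 1:
                out.update(family)
    return frozenset(out)


#: codons whose third position is four-fold degenerate (any base, same residue)
FOURFOLD_CODONS: frozenset[str] = _fourfold_codons()


def is_fourfold_third_position(codon: str) -> bool:
    return codon in FOURFOLD_CODONS


def substituted(codon: str, pos: int, base: str) -> str:
    return codon[:pos] + base + codon[pos + 1:]


def synonymous_alternatives(codon: str, pos: int) -> list[str]:
    """Sense codons one substitution away at ``pos`` encoding the same residue."""
    aa = CODON_TO_AA[codon]
    return [
        c
        for b in BASES
        if b != codon[pos]
        for c in (substituted(codon, pos, b),)
        if c in CODON_TO_AA and CODON_TO_AA[c] == aa
    ]


def nonsynonymous_alternatives(codon: str, pos: int) -> list[str]:
    """Sense codons one substitution away at ``pos`` encoding a different residue.

    Stop codons are excluded: a simulated nonsynonymous change never truncates
    the reading frame.
    """
    aa = CODON_TO_AA[codon]
    return [
        c
        for b in BASES
        if b != codon[pos]
        for c in (substituted(codon, pos, b),)
        if c in CODON_TO_AA and CODON_TO_AA[c] != aa
    ]
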