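"""Codon-level helpers shared by the simulator and the dN/dS estimator.

The standard genetic code is taken from Biopython; everything here is a thin
layer of lookups (sense codons, transition/transversion tests, single-step
codon neighbourhoods) that the Nei-Gojobori machinery needs in hot loops.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"

_table = unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    if a == b:
        raise ValueError("not a substitution")
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def single_mutants(codon: str, position: int):
    """Yield (new_nt, mutant_codon) for the three single changes at position."""
    old = codon[position]
    for nt in NUCLEOTIDES:
        if nt != old:
            yield nt, codon[:position] + nt + codon[position + 1 :]


def codons_of(seq: str):
    """Split a CDS into codons, discarding a trailing partial codon."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
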