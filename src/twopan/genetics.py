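"""Standard genetic-code helpers shared across modules.

The codon table is taken from Biopython's standard (NCBI table 1) code;
stop codons are represented by ``"*"``.
"""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
STOP = "*"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard residues, alphabetical

#: codon (DNA, upper case) -> one-letter residue, "*" for stop
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = STOP

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def translate_codon(codon: str) -> str:
    """Translate one DNA codon; raises KeyError on non-ACGT bases."""
    return CODON_TO_AA[codon]


def translate(seq: str) -> str:
    """Translate a DNA string (length a multiple of 3) codon by codon."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return "".join(CODON_TO_AA[seq[i : i + 3]] for i in range(0, len(seq), 3))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codons_for(residue: str) -> tuple[str, ...]:
    """All codons encoding ``residue`` ("*" for stop), lexicographic order."""
    return tuple(c for c in ALL_CODONS if CODON_TO_AA[c] == residue)


def is_sense_codon(codon: str) -> bool:
    return CODON_TO_AA.get(codon, STOP) != STOP
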