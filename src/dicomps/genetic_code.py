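"""Standard genetic code, RNA alphabet.

Thin wrapper over Biopython's standard codon table providing the 61 sense
codons, the stop codons, per-codon translation to 3-letter amino-acid codes
and Watson-Crick complements — the vocabulary every other module shares.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

_TABLE = CodonTable.unambiguous_rna_by_id[1]

RNA_BASES = ("A", "C", "G", "U")

#: complement in RNA space (Watson-Crick partner)
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))

#: codon -> 3-letter amino-acid code, e.g. "AUA" -> "Ile"
CODON_TO_AA3: dict[str, str] = {
    c: seq3(aa) for c, aa in _TABLE.forward_table.items()
}

#: the 20 standard residues, 3-letter codes
STANDARD_AA3: frozenset[str] = frozenset(CODON_TO_AA3.values())

#: sense codons grouped by amino acid (synonymous families)
SYNONYMOUS_FAMILY: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA3.items() if a == aa))
    for aa in STANDARD_AA3
}


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA letters to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def reverse_complement(triplet: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(triplet))


def translate_codon(codon: str) -> str | None:
    """3-letter residue for a sense codon, None for stops/invalid."""
    return CODON_TO_AA3.get(codon)


def is_sense_codon(codon: str) -> bool:
    return codon in CODON_TO_AA3
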