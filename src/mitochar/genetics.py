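"""Genetic-code utilities shared across the package.

Everything here is parameterized by an NCBI translation-table id; the
package default is table 2 (vertebrate mitochondrial), under which AGA and
AGG are stop codons, ATA codes for Met and TGA for Trp.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

BASES = "ACGT"
DEFAULT_CODE = 2

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return (a in PURINES) == (b in PURINES) and a != b


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@lru_cache(maxsize=None)
def stop_codons(code_id: int = DEFAULT_CODE) -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    return frozenset(table.stop_codons)


@lru_cache(maxsize=None)
def sense_codons(code_id: int = DEFAULT_CODE) -> tuple[str, ...]:
    """All non-stop codons of the code, lexicographic order (60 for table 2)."""
    stops = stop_codons(code_id)
    return tuple(
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if a + b + c not in stops
    )


@lru_cache(maxsize=None)
def codon_to_aa(code_id: int = DEFAULT_CODE) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    return dict(table.forward_table)


def translate_codon(codon: str, code_id: int = DEFAULT_CODE) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    if codon in stop_codons(code_id):
        return "*"
    return codon_to_aa(code_id)[codon]


def translate(cds: str, code_id: int = DEFAULT_CODE) -> str:
    """Translate complete codons; trailing partial codon ignored."""
    n = len(cds) - len(cds) % 3
    return "".join(translate_codon(cds[i : i + 3], code_id) for i in range(0, n, 3))


@lru_cache(maxsize=None)
def synonymous_families(code_id: int = DEFAULT_CODE) -> dict[str, tuple[str, ...]]:
    """Map amino acid -> tuple of its codons under the code (stops excluded)."""
    fams: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa(code_id).items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cods)) for aa, cods in fams.items()}


def is_synonymous(a: str, b: str, code_id: int = DEFAULT_CODE) -> bool:
    """Both codons must be sense codons."""
    return translate_codon(a, code_id) == translate_codon(b, code_id)
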